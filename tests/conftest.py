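import numpy as np
import pytest

from t2ie import AcquisitionProtocol, build_fa_bank, build_t2_grid


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def grid():
    return build_t2_grid()


@pytest.fixture(scope="session")
def bank(protocol, grid):
    # session-scoped so dictionary matrices are built once across the suite
    return build_fa_bank(protocol, grid)


def isochromat_cpmg(t2, t1, fa_deg, protocol, n_iso=20_000):
    """Brute-force Bloch-rotation ensemble oracle for the CPMG echo train.

    Spins on a deterministic grid of dephasing angles experience a 90°
    excitation about y and refocusing rotations of ``fa_deg`` about x (the
    CPMG condition), with T2/T1 relaxation (no regrowth) and free
    precession over each half echo-spacing; echo amplitudes are the
    magnitude of the ensemble-mean transverse magnetization.  Independent
    of the EPG state recursion it validates.
    """
    n_echoes, dte = protocol.n_echoes, protocol.delta_te
    thetas = (np.arange(n_iso) + 0.5) / n_iso * 2 * np.pi
    e2 = np.exp(-dte / 2 / t2)
    e1 = np.exp(-dte / 2 / t1)
    a = np.deg2rad(fa_deg)
    m = np.zeros((n_iso, 3))
    m[:, 0] = 1.0  # after 90° about y
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    ca, sa = np.cos(a), np.sin(a)

    def free(m):
        m = m * np.array([e2, e2, e1])
        x = m[:, 0] * cos_t - m[:, 1] * sin_t
        y = m[:, 0] * sin_t + m[:, 1] * cos_t
        return np.stack([x, y, m[:, 2]], 1)

    echoes = np.empty(n_echoes)
    for n in range(n_echoes):
        m = free(m)
        y = ca * m[:, 1] + sa * m[:, 2]
        z = -sa * m[:, 1] + ca * m[:, 2]
        m = np.stack([m[:, 0], y, z], 1)
        m = free(m)
        echoes[n] = np.hypot(m[:, 0].mean(), m[:, 1].mean())
    return echoes
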