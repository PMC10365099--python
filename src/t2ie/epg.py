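"""Extended Phase Graph (EPG) simulation of multi-echo spin-echo trains.

A CPMG-style acquisition (90° excitation followed by a train of nominally
180° refocusing pulses) refocuses transverse magnetization at the midpoint
between pulses.  When the effective refocusing flip angle deviates from
180° — as it does in practice because of B1 inhomogeneity and slice-profile
effects — part of the magnetization is stored longitudinally between pulses
and returns later as stimulated echoes.  The EPG formalism tracks this
exactly by following the magnetization's Fourier configuration states
(F+(k), F-(k), Z(k)) through dephasing, relaxation and RF mixing, and is
the standard forward model for multi-component T2 dictionary fitting.

Conventions used here (all tested):

* unit initial magnetization, ideal 90° excitation;
* CPMG phase condition, so all states stay real and the echo amplitude is
  the magnitude of the zeroth-order transverse state F(0);
* longitudinal configuration states relax with T1 between pulses, but the
  equilibrium regrowth term is omitted so that echo amplitudes are
  independent of proton density recovery within the train (the usual
  convention for multi-echo T2 dictionaries);
* one unit of gradient dephasing per half echo-spacing.

At a flip angle of exactly 180° the recursion collapses to the
monoexponential decay ``exp(-TE_n / T2)`` for any T1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionProtocol", "epg_echo_amplitudes"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of a multi-echo spin-echo (GRASE/CPMG) acquisition.

    Parameters
    ----------
    n_echoes
        Number of acquired echoes.
    te_min
        First echo time in ms.
    delta_te
        Echo spacing in ms.  Echo ``n`` (1-based) occurs at
        ``te_min + (n - 1) * delta_te``.
    tr
        Repetition time in ms (bookkeeping only; the train simulation does
        not model inter-TR recovery).
    t1_assumed
        Longitudinal relaxation time in ms assumed by the EPG recursion for
        magnetization stored along z between refocusing pulses.  Set it very
        large to disable T1 relaxation entirely.
    """

    n_echoes: int = 32
    te_min: float = 10.68
    delta_te: float = 10.68
    tr: float = 1000.0
    t1_assumed: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if self.te_min <= 0 or self.delta_te <= 0:
            raise ValueError("te_min and delta_te must be positive")
        if self.tr <= 0 or self.t1_assumed <= 0:
            raise ValueError("tr and t1_assumed must be positive")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times TE_n in ms, length ``n_echoes``."""
        return self.te_min + self.delta_te * np.arange(self.n_echoes)


def _refocusing_matrix(fa_deg: float) -> np.ndarray:
    """3x3 EPG mixing matrix of a refocusing pulse of angle ``fa_deg``.

    Acts on the per-order state vector (F+, F-, Z) under the CPMG phase
    convention (real-valued states).
    """
    a = np.deg2rad(fa_deg)
    c2, s2, s = np.cos(a / 2.0) ** 2, np.sin(a / 2.0) ** 2, np.sin(a)
    return np.array(
        [
            [c2, s2, s],
            [s2, c2, -s],
            [-0.5 * s, 0.5 * s, np.cos(a)],
        ]
    )


def epg_echo_amplitudes(
    t2: float,
    t1: float,
    fa: float,
    protocol: AcquisitionProtocol | None = None,
) -> np.ndarray:
    """Echo amplitudes of a CPMG train for a single-T2 spin pool.

    Parameters
    ----------
    t2, t1
        Relaxation times in ms (both > 0).
    fa
        Effective refocusing flip angle in degrees, 0 < fa <= 180.
    protocol
        Acquisition timing; defaults to the 32-echo, 10.68 ms protocol.

    Returns
    -------
    numpy.ndarray
        Non-negative echo amplitudes, length ``protocol.n_echoes``, for
        unit initial magnetization (first entry <= 1).
    """
    if protocol is None:
        protocol = AcquisitionProtocol()
    if t2 <= 0 or t1 <= 0:
        raise ValueError("t2 and t1 must be positive")
    if not 0.0 < fa <= 180.0:
        raise ValueError("fa must be in (0, 180] degrees")

    n = protocol.n_echoes
    tau_half = protocol.delta_te / 2.0
    e2 = np.exp(-tau_half / t2)
    e1 = np.exp(-tau_half / t1)

    # Configuration orders 0..n+1: no pathway of an n-echo train can reach a
    # higher order and still return to F(0), so this is exact.
    n_orders = n + 2
    fp = np.zeros(n_orders)  # F(+k)
    fm = np.zeros(n_orders)  # F(-k); index 0 aliases F(0)
    z = np.zeros(n_orders)
    fp[0] = 1.0  # after ideal 90° excitation
    fm[0] = 1.0

    rot = _refocusing_matrix(fa)
    echoes = np.empty(n)
    for i in range(n):
        # half interval: relax, dephase by +1
        fp *= e2
        fm *= e2
        z *= e1
        fp[1:] = fp[:-1]
        fp[0] = fm[1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fm[0] = fp[0]
        # refocusing pulse
        fp, fm, z = (
            rot[0, 0] * fp + rot[0, 1] * fm + rot[0, 2] * z,
            rot[1, 0] * fp + rot[1, 1] * fm + rot[1, 2] * z,
            rot[2, 0] * fp + rot[2, 1] * fm + rot[2, 2] * z,
        )
        # half interval: relax, dephase by +1, read the echo at F(0)
        fp *= e2
        fm *= e2
        z *= e1
        fp[1:] = fp[:-1]
        fp[0] = fm[1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fm[0] = fp[0]
        echoes[i] = abs(fp[0])
    return echoes
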