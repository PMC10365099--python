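"""T2 grids, flip-angle grids, and EPG dictionary matrices.

Every fitting method in this package solves (or learns) the linear model
``y = A(FA) x`` where ``y`` is the measured echo train, ``x`` the
non-negative T2 spectrum on a fixed logarithmic grid, and ``A(FA)`` the
dictionary whose column ``j`` is the EPG echo train of the grid's j-th T2
at the voxel's effective refocusing flip angle.  Columns are raw EPG
amplitudes (unit proton density, not normalized); the amplitude scale is
absorbed by the spectrum weights.

Defaults follow the 3T multi-echo GRASE setting: 60 T2 nodes
logarithmically spaced over 10–2000 ms, a coarse grid of 15 equally spaced
flip angles in [90°, 180°] for flip-angle estimation, and a fine 0.33°-step
grid for the precomputed dictionary bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import AcquisitionProtocol, epg_echo_amplitudes

__all__ = [
    "T2Grid",
    "FAGrids",
    "DictionaryBank",
    "build_t2_grid",
    "build_dictionary",
    "build_fa_bank",
]


@dataclass(frozen=True)
class T2Grid:
    """Logarithmically spaced T2 values in ms (strictly increasing)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("T2 grid needs at least two values")
        if np.any(np.diff(v) <= 0):
            raise ValueError("T2 grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def log_spacing(self) -> float:
        """Constant log-spacing ln(v[j+1]/v[j]) of the grid."""
        return float(np.log(self.values[1] / self.values[0]))


def build_t2_grid(t2_lo: float = 10.0, t2_hi: float = 2000.0, n_t2: int = 60) -> T2Grid:
    """Inclusive log-spaced grid of ``n_t2`` T2 values from ``t2_lo`` to ``t2_hi``."""
    if t2_lo <= 0 or t2_hi <= t2_lo:
        raise ValueError("need 0 < t2_lo < t2_hi")
    if n_t2 < 2:
        raise ValueError("n_t2 must be >= 2")
    return T2Grid(np.geomspace(t2_lo, t2_hi, n_t2))


def _fine_fa_keys(step: float = 0.33) -> np.ndarray:
    # 90 + k*step for k = 0..floor(90/step); 180 appended exactly when the
    # step does not land on it (0.33 does not divide 90).
    k_max = int(np.floor(90.0 / step + 1e-9))
    keys = 90.0 + step * np.arange(k_max + 1)
    if not np.isclose(keys[-1], 180.0):
        keys = np.append(keys, 180.0)
    return keys


@dataclass(frozen=True)
class FAGrids:
    """Coarse (estimation) and fine (bank) refocusing flip-angle grids, degrees."""

    coarse: np.ndarray = field(default_factory=lambda: np.linspace(90.0, 180.0, 15))
    fine: np.ndarray = field(default_factory=_fine_fa_keys)

    def __post_init__(self) -> None:
        c = np.asarray(self.coarse, dtype=float)
        f = np.asarray(self.fine, dtype=float)
        if c[0] != 90.0 or c[-1] != 180.0:
            raise ValueError("coarse FA grid must span [90, 180]")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fine FA grid must be strictly increasing")
        object.__setattr__(self, "coarse", c)
        object.__setattr__(self, "fine", f)


def build_dictionary(
    protocol: AcquisitionProtocol, grid: T2Grid, fa: float
) -> np.ndarray:
    """EPG dictionary matrix of shape ``(n_echoes, n_t2)`` at flip angle ``fa``."""
    if not 90.0 <= fa <= 180.0:
        raise ValueError("fa must be in [90, 180] degrees")
    cols = [
        epg_echo_amplitudes(t2, protocol.t1_assumed, fa, protocol)
        for t2 in grid.values
    ]
    return np.column_stack(cols)


class DictionaryBank:
    """Lazy cache of per-FA dictionary matrices keyed by fine-grid FA values.

    ``lookup(fa)`` returns the matrix whose key minimizes ``|fa - key|``
    (ties to the smaller key); matrices are built on first use and cached,
    so lookups are bit-identical to eager construction.
    """

    def __init__(
        self,
        protocol: AcquisitionProtocol,
        grid: T2Grid,
        fa_grids: FAGrids | None = None,
    ):
        self.protocol = protocol
        self.grid = grid
        self.fa_grids = fa_grids if fa_grids is not None else FAGrids()
        self._cache: dict[float, np.ndarray] = {}

    @property
    def keys(self) -> np.ndarray:
        return self.fa_grids.fine

    def nearest_key(self, fa: float) -> float:
        keys = self.keys
        d = np.abs(keys - fa)
        # argmin returns the first (smaller) key on exact ties
        return float(keys[int(np.argmin(d))])

    def matrix_at_key(self, key: float) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = build_dictionary(self.protocol, self.grid, key)
        return self._cache[key]

    def lookup(self, fa: float) -> np.ndarray:
        """Dictionary matrix at the fine-grid key nearest to ``fa``."""
        return self.matrix_at_key(self.nearest_key(fa))

    def coarse_matrices(self) -> list[tuple[float, np.ndarray]]:
        """(FA, matrix) pairs for the 15 coarse flip angles.

        Coarse FAs are evaluated exactly (not snapped) so that flip-angle
        estimation sees the true coarse-grid dictionaries.
        """
        out = []
        for fa in self.fa_grids.coarse:
            fa = float(fa)
            if fa not in self._cache:
                self._cache[fa] = build_dictionary(self.protocol, self.grid, fa)
            out.append((fa, self._cache[fa]))
        return out


def build_fa_bank(
    protocol: AcquisitionProtocol,
    grid: T2Grid,
    fa_grids: FAGrids | None = None,
) -> DictionaryBank:
    """Construct the (lazily materialized) per-FA dictionary bank."""
    return DictionaryBank(protocol, grid, fa_grids)
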