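"""Regularized non-negative least squares estimation of T2 spectra.

The multi-echo inverse problem ``min ||A x - y||^2, x >= 0`` is severely
ill-posed: dictionary columns of neighbouring T2 values are nearly
collinear, so the unregularized solution is a few spikes that move wildly
with noise.  Both methods here add an identity Tikhonov penalty,

    min_x ||A x - y||^2 + lambda^2 ||x||^2,   x >= 0,

solved exactly as plain NNLS on the augmented system [A; lambda I] against
[y; 0], and differ only in how lambda is chosen:

* chi-square criterion: the largest lambda whose data residual stays within
  a fixed factor (default 1.02) of the unregularized minimum residual;
* L-curve criterion: the lambda at the corner of maximum curvature of the
  (log residual-norm^2, log solution-norm^2) curve, located by discrete
  Menger curvature and refined by golden-section search.

Spectra are kept in proton-density units (signals are not normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .dictionary import DictionaryBank, T2Grid
from .flip_angle import FAMap

__all__ = [
    "T2Spectrum",
    "FitConfig",
    "nnls",
    "reg_nnls",
    "select_lambda_chi2",
    "select_lambda_lcurve",
    "fit_volume",
]


@dataclass
class T2Spectrum:
    """Non-negative T2 spectrum on a grid, with the fit's bookkeeping."""

    weights: np.ndarray
    grid: T2Grid
    lambda_used: float = 0.0
    residual_sse: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("spectrum weights must be finite and non-negative")
        if self.lambda_used < 0:
            raise ValueError("lambda_used must be >= 0")
        self.weights = w


@dataclass
class FitConfig:
    """Spectral-fit configuration.

    ``lambda_grid`` defaults to 60 log-spaced points spanning
    ``[1e-5, 10] * lambda_ref`` where ``lambda_ref`` is the largest
    dictionary column norm — wide enough to bracket both under- and
    over-regularization for any signal scale the dictionary produces.
    """

    method: str = "chi2_identity"
    chi2_factor: float = 1.02
    n_lambda: int = 60
    lambda_span: tuple[float, float] = (1e-5, 10.0)
    lambda_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in ("chi2_identity", "lcurve_identity", "miml"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.chi2_factor <= 1:
            raise ValueError("chi2_factor must be > 1")

    def resolve_lambda_grid(self, a: np.ndarray) -> np.ndarray:
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
        else:
            lam_ref = float(np.max(np.linalg.norm(a, axis=0)))
            g = np.geomspace(
                self.lambda_span[0] * lam_ref, self.lambda_span[1] * lam_ref, self.n_lambda
            )
        if np.any(np.diff(g) <= 0) or np.any(g <= 0):
            raise ValueError("lambda grid must be positive and strictly increasing")
        return g


def nnls(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lawson–Hanson active-set solution of min ||A x - y||^2, x >= 0."""
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    if a.ndim != 2 or y.ndim != 1 or a.shape[0] != y.size:
        raise ValueError("dimension mismatch between A and y")
    x, _ = _scipy_nnls(a, y)
    return x


def reg_nnls(a: np.ndarray, y: np.ndarray, lam: float, grid: T2Grid | None = None) -> T2Spectrum:
    """Tikhonov-regularized NNLS via the augmented system [A; lam*I], [y; 0].

    ``residual_sse`` reports the data term ``||A x - y||^2`` only.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam == 0:
        x = nnls(a, y)
    else:
        n_t2 = a.shape[1]
        a_aug = np.vstack([a, lam * np.eye(n_t2)])
        y_aug = np.concatenate([y, np.zeros(n_t2)])
        x = nnls(a_aug, y_aug)
    sse = float(np.sum((a @ x - y) ** 2))
    if grid is None:
        grid = T2Grid(np.arange(1.0, a.shape[1] + 1.0))  # index placeholder grid
    return T2Spectrum(x, grid, lambda_used=float(lam), residual_sse=sse)


def select_lambda_chi2(
    a: np.ndarray,
    y: np.ndarray,
    cfg: FitConfig | None = None,
    grid: T2Grid | None = None,
) -> T2Spectrum:
    """Chi-square residual criterion: largest lambda with
    ``residual <= chi2_factor * residual(lambda=0)``, bisected between the
    bracketing grid points to a relative tolerance of 1e-3 on the factor.
    """
    cfg = cfg or FitConfig(method="chi2_identity")
    y = np.asarray(y, dtype=float)
    if not np.any(y != 0):
        raise ValueError("y must not be all zero")
    lam_grid = cfg.resolve_lambda_grid(a)
    base = reg_nnls(a, y, 0.0, grid)
    chi2_min = base.residual_sse
    if chi2_min <= 0.0:
        out = reg_nnls(a, y, lam_grid[0], grid)
        if out.residual_sse > 0:  # perfect fit only at lam -> 0
            out = base
        out.degenerate = True
        return out
    target = cfg.chi2_factor * chi2_min

    # walk up the grid until the residual exceeds the target
    lo, hi = 0.0, None
    sol_lo = base
    for lam in lam_grid:
        sol = reg_nnls(a, y, lam, grid)
        if sol.residual_sse <= target:
            lo, sol_lo = lam, sol
        else:
            hi = lam
            break
    if hi is None:  # even the largest lambda stays inside the target
        return sol_lo
    # bisection on lambda between the bracketing grid points
    rel_tol = 1e-3 * chi2_min
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        sol = reg_nnls(a, y, mid, grid)
        if sol.residual_sse <= target:
            lo, sol_lo = mid, sol
        else:
            hi = mid
        if abs(sol.residual_sse - target) <= rel_tol or (hi - lo) < 1e-12 * max(hi, 1.0):
            break
    return sol_lo


def _menger_curvature(p1, p2, p3) -> float:
    """Curvature of the circumcircle through three 2D points (0 if collinear)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    area2 = abs(
        (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p3[0] - p1[0]) * (p2[1] - p1[1])
    )
    d12 = np.hypot(*(p2 - p1))
    d23 = np.hypot(*(p3 - p2))
    d13 = np.hypot(*(p3 - p1))
    denom = d12 * d23 * d13
    if denom == 0:
        return 0.0
    return 2.0 * area2 / denom


def _lcurve_point(a, y, lam, grid, floor):
    sol = reg_nnls(a, y, lam, grid)
    res = max(sol.residual_sse, floor)
    norm = max(float(np.sum(sol.weights**2)), floor)
    return sol, np.array([np.log(res), np.log(norm)])


def select_lambda_lcurve(
    a: np.ndarray,
    y: np.ndarray,
    cfg: FitConfig | None = None,
    grid: T2Grid | None = None,
) -> T2Spectrum:
    """L-curve corner criterion (maximum discrete Menger curvature).

    Falls back to the smallest grid lambda with a warning when the curve is
    degenerate (all residuals equal, e.g. noise-free data fit exactly at
    every lambda).
    """
    cfg = cfg or FitConfig(method="lcurve_identity")
    y = np.asarray(y, dtype=float)
    if not np.any(y != 0):
        raise ValueError("y must not be all zero")
    lam_grid = cfg.resolve_lambda_grid(a)
    floor = 1e-300

    sols, pts = [], []
    for lam in lam_grid:
        sol, pt = _lcurve_point(a, y, lam, grid, floor)
        sols.append(sol)
        pts.append(pt)
    pts_arr = np.array(pts)

    if sols[0].residual_sse <= 1e-10 * float(np.sum(y**2)):
        # numerically exact fit at the weakest regularization: the L-curve
        # has no meaningful corner and no smoothing is needed
        warnings.warn("exact fit at smallest lambda: L-curve degenerate", stacklevel=2)
        sols[0].degenerate = True
        return sols[0]
    if np.ptp(pts_arr[:, 0]) < 1e-12:
        warnings.warn("degenerate L-curve (flat residual): falling back to smallest lambda",
                      stacklevel=2)
        return sols[0]

    curv = np.array(
        [_menger_curvature(pts_arr[i - 1], pts_arr[i], pts_arr[i + 1])
         for i in range(1, len(lam_grid) - 1)]
    )
    if np.max(curv) < 1e-9:  # collinear within numerical noise
        warnings.warn("collinear L-curve: falling back to smallest lambda", stacklevel=2)
        return sols[0]
    # ties in the curvature maximum go to the smaller lambda (argmax order)
    i_best = 1 + int(np.argmax(curv))

    # golden-section refinement of the corner between the bracketing grid
    # points, scoring candidate lambdas by curvature against the fixed
    # outer neighbours
    lo, hi = lam_grid[i_best - 1], lam_grid[i_best + 1]
    p_lo, p_hi = pts_arr[i_best - 1], pts_arr[i_best + 1]
    best_sol, best_curv = sols[i_best], curv[i_best - 1]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    s1, q1 = _lcurve_point(a, y, x1, grid, floor)
    s2, q2 = _lcurve_point(a, y, x2, grid, floor)
    f1 = _menger_curvature(p_lo, q1, p_hi)
    f2 = _menger_curvature(p_lo, q2, p_hi)
    for _ in range(20):
        if f1 > f2:
            hi, x2, s2, f2 = x2, x1, s1, f1
            x1 = hi - invphi * (hi - lo)
            s1, q1 = _lcurve_point(a, y, x1, grid, floor)
            f1 = _menger_curvature(p_lo, q1, p_hi)
        else:
            lo, x1, s1, f1 = x1, x2, s2, f2
            x2 = lo + invphi * (hi - lo)
            s2, q2 = _lcurve_point(a, y, x2, grid, floor)
            f2 = _menger_curvature(p_lo, q2, p_hi)
        if (hi - lo) < 1e-3 * lo:
            break
    for s, f in ((s1, f1), (s2, f2)):
        if f > best_curv:
            best_sol, best_curv = s, f
    return best_sol


def fit_volume(
    image4d: np.ndarray,
    mask: np.ndarray,
    fa_map: FAMap,
    bank: DictionaryBank,
    cfg: FitConfig | None = None,
) -> dict[tuple, T2Spectrum]:
    """Per-voxel spectral fit over a mask.

    Each voxel's echo train is fitted against the bank matrix at the fine
    FA key nearest to the voxel's estimated flip angle, with the configured
    lambda-selection criterion.  Voxels without an FA estimate are skipped.

    Returns a dict mapping voxel index tuples to fitted spectra.
    """
    cfg = cfg or FitConfig()
    image4d = np.asarray(image4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image4d.shape[:3] != mask.shape:
        raise ValueError("image and mask are not co-registered")
    select = select_lambda_chi2 if cfg.method == "chi2_identity" else select_lambda_lcurve
    if cfg.method == "miml":
        raise ValueError("use t2ie.miml.predict_spectrum_map for the MIML method")
    out: dict[tuple, T2Spectrum] = {}
    skipped = 0
    for idx in zip(*np.nonzero(mask)):
        fa = fa_map.values[idx]
        if not np.isfinite(fa):
            skipped += 1
            continue
        a = bank.lookup(float(fa))
        y = image4d[idx]
        if not np.any(y != 0):
            skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[idx] = select(a, y, cfg, bank.grid)
    if skipped:
        warnings.warn(f"{skipped} voxel(s) skipped (no FA estimate or zero signal)",
                      stacklevel=2)
    return out
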