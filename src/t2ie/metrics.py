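"""Scalar maps derived from T2 spectra: T2IE and myelin water fraction.

The T2 spectrum of brain tissue at 3T separates into a myelin-water lobe
(T2 < 40 ms), an intra/extra-cellular (IE) lobe (40–200 ms) and free water
(T2 > 200 ms).  T2IE is the amplitude-weighted geometric mean of the
spectrum restricted to the IE window,

    T2IE = exp( sum_{i in W} w_i ln T2_i / sum_{i in W} w_i ),

which makes it scale-invariant in the weights and — because mass outside
the window never enters the sum — immune to partial-volume contamination
from myelin or free water.  MWF is the fraction of total spectral mass
below the myelin cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnls_fit import T2Spectrum

__all__ = ["CompartmentWindows", "t2ie", "mwf"]


@dataclass(frozen=True)
class CompartmentWindows:
    """T2 cutoffs in ms separating myelin, IE and free-water pools (inclusive)."""

    myelin_upper: float = 40.0
    free_water_lower: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.myelin_upper < self.free_water_lower:
            raise ValueError("need 0 < myelin_upper < free_water_lower")


def t2ie(spectrum: T2Spectrum, windows: CompartmentWindows | None = None) -> float:
    """Weighted geometric-mean T2 over the IE window, or NaN if the window is empty."""
    windows = windows or CompartmentWindows()
    t2v = spectrum.grid.values
    w = spectrum.weights
    in_win = (t2v >= windows.myelin_upper) & (t2v <= windows.free_water_lower)
    mass = w[in_win].sum()
    if mass <= 0:
        return float("nan")
    return float(np.exp(np.dot(w[in_win], np.log(t2v[in_win])) / mass))


def mwf(spectrum: T2Spectrum, windows: CompartmentWindows | None = None) -> float:
    """Myelin water fraction: spectral mass with T2 < myelin_upper over total mass."""
    windows = windows or CompartmentWindows()
    w = spectrum.weights
    total = w.sum()
    if total <= 0:
        return float("nan")
    return float(w[spectrum.grid.values < windows.myelin_upper].sum() / total)
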