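"""Summary statistics of nonnegative mass profiles on a 20-bp bin grid."""

from __future__ import annotations

import numpy as np

#: Grid conventions shared across the package: 20-bp bins; DSB-relative
#: binding profiles live on k in {K_LO..K_HI} (-1000..+2500 bp).
BIN_WIDTH = 20
K_LO = -50
K_HI = 125


def peak_bp(mass: np.ndarray, k_lo: int, bin_width: int = 20) -> float:
    """Midpoint (bp) of the maximal bin; exact ties resolve to smallest |bp|."""
    mass = np.asarray(mass, dtype=float)
    mx = mass.max()
    ties = np.flatnonzero(mass == mx)
    bp = (ties + k_lo) * bin_width
    return float(bp[np.argmin(np.abs(bp))])


def binned_quantiles(mass: np.ndarray, k_lo: int, qs, bin_width: int = 20) -> np.ndarray:
    """Quantiles of a binned mass distribution, linear within each bin.

    Bin ``k`` covers ``[w*(k - 1/2), w*(k + 1/2))``; mass is treated as
    uniform within its bin, so the cumulative distribution is piecewise
    linear between bin edges.
    """
    mass = np.asarray(mass, dtype=float)
    if np.any(mass < 0):
        raise ValueError("mass must be nonnegative")
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero-mass profile")
    cum = np.concatenate([[0.0], np.cumsum(mass)]) / total
    edges = (np.arange(k_lo, k_lo + len(mass) + 1) - 0.5) * bin_width
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    out = np.empty_like(qs)
    for i, q in enumerate(qs):
        j = int(np.searchsorted(cum, q, side="left"))
        j = min(max(j, 1), len(mass))
        dq = cum[j] - cum[j - 1]
        frac = 0.0 if dq == 0 else (q - cum[j - 1]) / dq
        out[i] = edges[j - 1] + frac * bin_width
    return out


def smooth_moving_average(values: np.ndarray, window_bp: int, bin_width: int = 20) -> np.ndarray:
    """Centered moving average over ``window_bp`` (rounded to an odd bin count)."""
    values = np.asarray(values, dtype=float)
    nbins = max(1, int(round(window_bp / bin_width)))
    if nbins % 2 == 0:
        nbins += 1
    if nbins == 1:
        return values.copy()
    kernel = np.full(nbins, 1.0 / nbins)
    return np.convolve(values, kernel, mode="same")
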