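"""Geometry of recombinase foci on chromosome spreads.

Operates on coordinates (nm): focus points per channel (RAD51, DMC1) and
chromosome-axis polylines (SYCP3), answering how far foci sit from axes,
which foci pair into co-foci across channels, and whether far-off-axis foci
look like uniform background.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

CO_FOCUS_THRESHOLD_NM = 300.0
OFF_AXIS_CUTOFF_NM = 450.0

__all__ = [
    "distance_to_axis",
    "distances_to_axes",
    "pair_cofoci",
    "axis_proximity_compare",
    "offaxis_uniformity",
]


def _segments(axes) -> tuple[np.ndarray, np.ndarray]:
    """Stack all polyline segments as (starts, ends), validating vertex counts."""
    starts, ends = [], []
    for poly in axes:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
            raise ValueError("each axis polyline needs >= 2 (x, y) vertices")
        starts.append(poly[:-1])
        ends.append(poly[1:])
    if not starts:
        raise ValueError("empty axis set")
    return np.concatenate(starts), np.concatenate(ends)


def distance_to_axis(point, axes) -> float:
    """Minimum Euclidean distance from one point to any axis segment."""
    return float(distances_to_axes(np.asarray(point, float)[None, :], axes)[0])


def distances_to_axes(points, axes) -> np.ndarray:
    """Vectorized point-to-polyline distances (nm) for many foci."""
    points = np.asarray(points, dtype=float)
    a, b = _segments(axes)
    ab = b - a                                    # (s, 2)
    ap = points[:, None, :] - a[None, :, :]       # (n, s, 2)
    denom = (ab * ab).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def pair_cofoci(foci_a, foci_b, threshold: float = CO_FOCUS_THRESHOLD_NM) -> dict:
    """Nearest-opposite-channel pairing and co-focus fractions.

    A focus is in a co-focus iff its nearest focus of the other channel is
    within ``threshold`` nm (per-focus nearest neighbor, not mutual).
    Returns per-channel co-focus fractions, flags, and the nearest-neighbor
    offsets of the flagged foci.
    """
    foci_a = np.asarray(foci_a, dtype=float).reshape(-1, 2)
    foci_b = np.asarray(foci_b, dtype=float).reshape(-1, 2)
    if len(foci_a) == 0 or len(foci_b) == 0:
        empty = np.zeros(0)
        return {"fraction_a": 0.0, "fraction_b": 0.0,
                "flag_a": np.zeros(len(foci_a), bool),
                "flag_b": np.zeros(len(foci_b), bool),
                "offsets_a": empty, "offsets_b": empty}
    from scipy.spatial.distance import cdist

    d = cdist(foci_a, foci_b)
    nn_a = d.min(axis=1)
    nn_b = d.min(axis=0)
    flag_a = nn_a <= threshold
    flag_b = nn_b <= threshold
    return {
        "fraction_a": float(flag_a.mean()),
        "fraction_b": float(flag_b.mean()),
        "flag_a": flag_a,
        "flag_b": flag_b,
        "offsets_a": nn_a[flag_a],
        "offsets_b": nn_b[flag_b],
    }


def axis_proximity_compare(distances_a, distances_b) -> dict:
    """Medians per channel plus a Welch two-sample t-test on axis distances."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 distances")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if np.median(a) == np.median(b) else (np.inf, float("nan"))
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "t": float(t),
        "p": float(p),
    }


def offaxis_uniformity(distances, cutoff: float = OFF_AXIS_CUTOFF_NM,
                       field_extent: float = None, min_points: int = 10) -> dict:
    """Kolmogorov-Smirnov test of far-off-axis distances against uniformity.

    Distances beyond ``cutoff`` from randomly scattered background points
    are expected uniform on ``(cutoff, field_extent]``; a small p rejects
    the background interpretation.
    """
    distances = np.asarray(distances, dtype=float)
    tail = distances[distances > cutoff]
    if len(tail) < min_points:
        raise ValueError(
            f"only {len(tail)} distances beyond {cutoff} nm (need {min_points})"
        )
    if field_extent is None or field_extent <= cutoff:
        raise ValueError("field_extent must exceed the cutoff")
    stat, p = stats.kstest(tail, stats.uniform(loc=cutoff,
                                               scale=field_extent - cutoff).cdf)
    return {"n": int(len(tail)), "ks_stat": float(stat), "p": float(p)}
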