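"""Per-hotspot signal extraction: intensities, homolog fractions, aggregates.

Works on :class:`~meiomap.profiles.StrandProfile` coverage and produces the
quantities the downstream analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binstats import smooth_moving_average
from .profiles import StrandProfile, check_same_binning

ASYMMETRY_THRESHOLD = 0.9  # f >= 0.9 or f <= 0.1 defines an asymmetric hotspot


@dataclass
class HotspotRecord:
    """One hotspot: PRDM9-motif midpoint, allele, homolog fraction, signal."""

    chrom: str
    center: int
    allele: str = ""
    f: float = np.nan
    spo11_count: float = 0.0
    centromere_distance: float = np.nan
    intensity: dict | None = None


def hotspot_intensity(profile: StrandProfile, hotspot_width: int = 500,
                      binding_width: int = 2000, flank: tuple = (4000, 5000)) -> float:
    """Strand-aware, background-adjusted read mass of one hotspot.

    Background-corrected Crick coverage is summed over
    ``[-hotspot_width/2, +binding_width]`` and Watson over the mirrored
    window; the per-strand background is the flank mean (Crick left flank,
    Watson right), with negatives clamped, so the result is never negative.
    """
    required = max(binding_width, flank[1])
    if profile.span < required:
        raise ValueError(
            f"profile span {profile.span} bp too small: intensity estimation "
            f"requires at least ±{required} bp"
        )
    from .deconvolution import background_correct

    corrected = background_correct(profile, flank)
    centers = corrected.bin_centers()
    half = hotspot_width / 2
    crick_win = (centers >= -half) & (centers <= binding_width)
    watson_win = (centers >= -binding_width) & (centers <= half)
    return float(corrected.crick[crick_win].sum() + corrected.watson[watson_win].sum())


def homolog_fraction(reads_hom1: int, reads_hom2: int) -> tuple[float, tuple]:
    """Fraction of allele-informative reads from homolog 1, with a 95% CI.

    Returns ``(nan, (nan, nan))`` when there are no informative reads; such
    hotspots are excluded downstream.
    """
    if reads_hom1 < 0 or reads_hom2 < 0:
        raise ValueError("read counts must be nonnegative")
    total = reads_hom1 + reads_hom2
    if total == 0:
        return float("nan"), (float("nan"), float("nan"))
    from scipy.stats import binomtest

    f = reads_hom1 / total
    ci = binomtest(int(reads_hom1), int(total)).proportion_ci(0.95)
    return float(f), (float(ci.low), float(ci.high))


def classify_asymmetric(f: float, threshold: float = ASYMMETRY_THRESHOLD) -> str:
    """Label a hotspot by homolog fraction; the threshold is inclusive."""
    if np.isnan(f):
        return "undefined"
    if f >= threshold:
        return "asymmetric_hom1"
    if 1.0 - f >= threshold:  # not `f <= 1 - threshold`: keeps f = 0.1 inclusive
        return "asymmetric_hom2"
    return "symmetric"


def aggregate_profile(profiles, weights=None, smoothing_window: int = 100,
                      order_by=None) -> StrandProfile:
    """Weighted mean profile with a centered moving-average smoothing.

    ``order_by`` (e.g. per-hotspot SPO11 counts) is accepted for heatmap
    export: it does not change the mean but fixes the row order returned by
    :func:`heatmap_matrix`.
    """
    check_same_binning(profiles)
    if weights is None:
        weights = np.ones(len(profiles))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(profiles):
        raise ValueError("one weight per profile required")
    wsum = weights.sum()
    crick = np.sum([w * p.crick for w, p in zip(weights, profiles)], axis=0) / wsum
    watson = np.sum([w * p.watson for w, p in zip(weights, profiles)], axis=0) / wsum
    bw = profiles[0].bin_width
    return StrandProfile(
        smooth_moving_average(crick, smoothing_window, bw),
        smooth_moving_average(watson, smoothing_window, bw),
        bin_width=bw,
    )


def heatmap_matrix(profiles, order_by) -> np.ndarray:
    """Strand-summed per-hotspot rows sorted by descending ``order_by``."""
    check_same_binning(profiles)
    order = np.argsort(np.asarray(order_by))[::-1]
    return np.array([profiles[i].total() for i in order])


def strand_area_ratio(profiles) -> float:
    """Watson / Crick total area over a hotspot set (strand-balance check)."""
    if isinstance(profiles, StrandProfile):
        profiles = [profiles]
    crick = float(np.sum([p.crick.sum() for p in profiles]))
    watson = float(np.sum([p.watson.sum() for p in profiles]))
    if crick == 0:
        raise ValueError("zero Crick area")
    return watson / crick


def group_elevation(intensity, spo11, labels, baseline=None, min_group: int = 10) -> dict:
    """Per-group zero-intercept slope of intensity on SPO11 count, and ratios.

    The slope ``sum(x*y)/sum(x^2)`` measures signal per DSB within each
    group; slope ratios relative to ``baseline`` (default: first label in
    sorted order) quantify elevation, e.g. of X-chromosome over autosomal
    hotspots.
    """
    intensity = np.asarray(intensity, dtype=float)
    spo11 = np.asarray(spo11, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    slopes = {}
    for g in groups:
        sel = labels == g
        if sel.sum() < min_group:
            raise ValueError(f"group {g!r} has fewer than {min_group} hotspots")
        x, y = spo11[sel], intensity[sel]
        denom = float((x * x).sum())
        if denom == 0:
            raise ValueError(f"group {g!r} is degenerate: all-zero SPO11 counts")
        slopes[g] = float((x * y).sum() / denom)
    if baseline is None:
        baseline = groups[0]
    ratios = {g: slopes[g] / slopes[baseline] for g in groups}
    return {"slopes": slopes, "ratios": ratios, "baseline": baseline}
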