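"""Standard desk-scale recovery experiments.

Each function simulates data under the study conditions (2,000 hotspots,
truncated-Gaussian DSB offsets with sd 150 bp bounded at ±1 kb, Poisson
read depth 100 per hotspot), runs the corresponding analysis, and returns
the recovered quantity.  They are shared by the acceptance checks, the
test suite and the analysis drivers so every reported number comes from
the same code path.
"""

from __future__ import annotations

import numpy as np

from .deconvolution import background_correct, deconvolve, profile_stats
from .dloop import estimate_lifespans
from .kernels import BindingKernel, default_kernel
from .mixture import fit_mixture, normalize_area
from .profiles import sum_profiles
from .synthetic import (GeneratorConfig, OffsetModel, pooled_offset_distribution,
                        simulate_coverage, simulate_hotspots)

STUDY_N_HOTSPOTS = 2000
STUDY_DEPTH = 100.0
STUDY_OFFSET_SD = 150.0


def study_config(seed: int, n_hotspots: int = STUDY_N_HOTSPOTS) -> GeneratorConfig:
    """Plain (unskewed, symmetric) hotspot set under the standard conditions."""
    return GeneratorConfig(
        n_hotspots=n_hotspots,
        dsb_offset_model=OffsetModel(sd=STUDY_OFFSET_SD),
        skew_fraction=0.0,
        asym_fraction=0.0,
        seed=seed,
    )


def _deconvolved_track(kernel: BindingKernel, seed: int,
                       n_hotspots: int = STUDY_N_HOTSPOTS,
                       depth: float = STUDY_DEPTH, tol: float = 0.2):
    cfg = study_config(seed, n_hotspots)
    rng = cfg.rng()
    hotspots, offsets = simulate_hotspots(cfg, rng)
    sbar = pooled_offset_distribution(offsets)
    profiles = simulate_coverage(hotspots, kernel, depth, rng, offsets=offsets)
    agg = background_correct(sum_profiles(profiles))
    return deconvolve(agg, agg, sbar, tol=tol)


def recovered_profile_summary(protein: str, seed: int,
                              n_hotspots: int = STUDY_N_HOTSPOTS,
                              depth: float = STUDY_DEPTH,
                              smooth_bp: int = 100) -> dict:
    """Peak/median/central-95% of the deconvolved profile recovered from
    synthetic coverage generated with the protein's default kernel."""
    dp = _deconvolved_track(default_kernel(protein), seed, n_hotspots, depth)
    return profile_stats(dp, smooth_bp=smooth_bp)


def mixture_recovery(seed: int, weights=(0.65, 0.35),
                     n_hotspots: int = STUDY_N_HOTSPOTS,
                     depth: float = STUDY_DEPTH) -> float:
    """Percent DMC1 recovered by the mixture fit from synthetic RPA coverage
    composed as ``weights`` of the default DMC1 and RAD51 kernels.

    One shared hotspot set and offset distribution serve all three tracks,
    as in the real study; the fit uses the strand-averaged deconvolved
    profiles normalized to unit area.
    """
    cfg = study_config(seed, n_hotspots)
    rng = cfg.rng()
    hotspots, offsets = simulate_hotspots(cfg, rng)
    sbar = pooled_offset_distribution(offsets)
    kd, kr = default_kernel("DMC1"), default_kernel("RAD51")
    w_d, w_r = weights
    composed = BindingKernel(w_d * kd.on_full_grid() + w_r * kr.on_full_grid(),
                             name="RPA_composed")
    tracks = {}
    for name, kern in (("P", composed), ("D", kd), ("R", kr)):
        profiles = simulate_coverage(hotspots, kern, depth, rng, offsets=offsets)
        agg = background_correct(sum_profiles(profiles))
        dp = deconvolve(agg, agg, sbar, tol=0.2)
        tracks[name] = normalize_area(dp.b_mean)
    fit = fit_mixture(tracks["P"], tracks["D"], tracks["R"])
    return 100.0 * fit.prop_dmc1


def lifespan_recovery(seed: int, ratio: float = 2.6,
                      co_rates=(0.04, 0.08, 0.12, 0.16),
                      noise_sd: float = 0.01) -> float:
    """Lifespan ratio recovered from synthetic distance bins.

    Per-DSB template RPA in each bin is ``c*L_co + (1-c)*L_nco`` with
    ``L_nco = 1`` and ``L_co = ratio``, multiplied by i.i.d. lognormal-like
    noise factors (sd ``noise_sd``); the least-squares system is then
    solved for the two lifespans.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(co_rates, dtype=float)
    template = (c * ratio + (1.0 - c) * 1.0) * (1.0 + noise_sd * rng.standard_normal(len(c)))
    return estimate_lifespans(c, template).ratio
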