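"""End-to-end orchestration: simulate -> extract -> deconvolve -> mixture ->
skew -> dloop -> tracts -> foci, with per-stage seeds, a run log, and a
manifest stamping every output with the config hash and seed."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .binstats import BIN_WIDTH
from .deconvolution import background_correct, deconvolve, profile_stats
from .dloop import (bin_fractions, equal_signal_bins, estimate_lifespans,
                    rescale_crossover_rate, select_features,
                    standardize_predictors)
from .extraction import (classify_asymmetric, hotspot_intensity,
                         strand_area_ratio)
from .foci import (axis_proximity_compare, distances_to_axes, offaxis_uniformity,
                   pair_cofoci)
from .kernels import BindingKernel
from .mixture import fit_mixture, fixed_mixture_fit, normalize_area
from .profiles import sum_profiles
from .skew import classify_and_orient, half_signal_point, side_balance_test
from .synthetic import (GeneratorConfig, axes_polylines,
                        pooled_offset_distribution, simulate_coverage,
                        simulate_foci, simulate_hotspots, simulate_outcomes)
from .tracts import (breakpoint_probability_map, deconvolve_single,
                     nco_tract_map, rebin_map, tract_containment)

logger = logging.getLogger("meiomap")

ALL_STAGES = ("simulate", "extract", "deconvolve", "mixture", "skew",
              "dloop", "tracts", "foci")
_STAGE_SEEDS = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the study's stated values
    (20-bp bins, tol 0.2, 150-bp skew threshold, f 0.9/0.1, 300 nm,
    100,000 bootstrap iterations, 10% crossover share)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    out_dir: str = "meiomap_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    tol: float = 0.2
    skew_threshold_bp: float = 150.0
    asym_threshold: float = 0.9
    cofocus_threshold_nm: float = 300.0
    bootstrap_iterations: int = 100_000
    co_share: float = 0.10
    sister_fraction: float = 0.0
    n_bins: int = 4
    smoothing_bp: int = 100
    write_bedgraph: bool = False

    def validate(self) -> None:
        self.generator.validate()
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        deps = {"extract": ("simulate",), "deconvolve": ("simulate",),
                "mixture": ("simulate", "deconvolve"),
                "skew": ("simulate",), "dloop": ("simulate", "extract"),
                "tracts": ("simulate",), "foci": ("simulate",)}
        enabled = set(self.stages)
        for stage in enabled:
            missing = set(deps.get(stage, ())) - enabled
            if missing:
                raise ValueError(f"stage {stage!r} is missing required input "
                                 f"stages: {sorted(missing)}")

    def config_hash(self) -> str:
        payload = repr(dataclasses.asdict(self.generator)) + repr(
            {k: v for k, v in dataclasses.asdict(self).items() if k != "generator"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_rng(config: RunConfig, stage: str, salt: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence([config.seed, _STAGE_SEEDS[stage], salt])
    return np.random.default_rng(ss)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written)."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}, "outputs": []}
    ctx: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.time()
            logger.info("stage %s: start", stage)
            outputs = _STAGE_FUNCS[stage](config, ctx, out)
            manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                         "outputs": outputs}
            manifest["outputs"].extend(outputs)
            logger.info("stage %s: done (%.1fs)", stage, time.time() - t0)
        io.write_json(manifest, out / "manifest.json")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest


def _rpa_dsb_kernel(gen: GeneratorConfig) -> BindingKernel:
    wd, wr = gen.rpa_dsb_mix
    dens = (wd * gen.kernel("DMC1").on_full_grid()
            + wr * gen.kernel("RAD51").on_full_grid())
    return BindingKernel(dens, name="RPA_DSB")


def _stage_simulate(config: RunConfig, ctx: dict, out: Path) -> list:
    gen = config.generator
    rng = _stage_rng(config, "simulate")
    hotspots, offsets = simulate_hotspots(gen, rng)
    sbar = pooled_offset_distribution(offsets)
    kernels = {"DMC1": gen.kernel("DMC1"), "RAD51": gen.kernel("RAD51"),
               "RPA_DSB": _rpa_dsb_kernel(gen),
               "RPA_TEMPLATE": gen.kernel("RPA_TEMPLATE")}
    # template-RPA amount per DSB encodes intermediate lifespans: hotspots
    # more likely to resolve as crossovers accumulate more template signal
    c = hotspots["co_rate"].to_numpy()
    lifespan = c * gen.lifespan_ratio + (1.0 - c)
    template_scale = lifespan / lifespan.mean()
    profiles = {}
    for name, kern in kernels.items():
        profiles[name] = simulate_coverage(
            hotspots, kern, gen.read_depth, rng, offsets=offsets,
            skew_factor=gen.skew_factor, background=gen.read_background,
            overdispersion=gen.overdispersion,
            apply_skew=(name != "RPA_TEMPLATE"),
            depth_scale=template_scale if name == "RPA_TEMPLATE" else None)
    co, nco = simulate_outcomes(hotspots, gen, _stage_rng(config, "simulate", 1))
    axes, foci = simulate_foci(gen, _stage_rng(config, "simulate", 2))
    ctx.update(hotspots=hotspots, offsets=offsets, sbar=sbar,
               profiles=profiles, co=co, nco=nco, axes=axes, foci=foci)
    io.write_hotspots(hotspots, out / "hotspots.tsv")
    io.write_offsets(sbar, out / "spo11_offsets.tsv")
    io.config_to_yaml(gen, out / "generator_config.yaml")
    io.write_crossovers(co, out / "crossovers.tsv")
    io.write_ncos(nco, out / "noncrossovers.tsv")
    io.write_foci(foci, out / "foci.tsv")
    io.write_axes(axes, out / "axes.tsv")
    written = ["hotspots.tsv", "spo11_offsets.tsv", "generator_config.yaml",
               "crossovers.tsv", "noncrossovers.tsv", "foci.tsv", "axes.tsv"]
    for name, profs in profiles.items():
        agg = sum_profiles(profs)
        io.write_track(agg.bin_centers(), agg.crick,
                       out / f"coverage_{name}_crick.tsv", "coverage")
        io.write_track(agg.bin_centers(), agg.watson,
                       out / f"coverage_{name}_watson.tsv", "coverage")
        written += [f"coverage_{name}_crick.tsv", f"coverage_{name}_watson.tsv"]
        if config.write_bedgraph:
            io.write_coverage_bedgraph(profs, out / f"{name}_crick.bedgraph",
                                       out / f"{name}_watson.bedgraph")
            written += [f"{name}_crick.bedgraph", f"{name}_watson.bedgraph"]
    return written


def _stage_extract(config: RunConfig, ctx: dict, out: Path) -> list:
    hotspots = ctx["hotspots"]
    table = hotspots[["chrom", "center", "allele", "f", "spo11_count"]].copy()
    summary = {}
    for name, profs in ctx["profiles"].items():
        table[f"intensity_{name}"] = [hotspot_intensity(p) for p in profs]
        summary[f"strand_area_ratio_{name}"] = strand_area_ratio(profs)
    table["asymmetry"] = [classify_asymmetric(f, config.asym_threshold)
                          for f in hotspots["f"]]
    ctx["intensity"] = table
    table.to_csv(out / "intensity.tsv", sep="\t", index=False)
    io.write_json(summary, out / "extract_summary.json")
    return ["intensity.tsv", "extract_summary.json"]


def _stage_deconvolve(config: RunConfig, ctx: dict, out: Path) -> list:
    written = []
    summary = {}
    ctx["deconvolved"] = {}
    for name, profs in ctx["profiles"].items():
        agg = background_correct(sum_profiles(profs))
        dp = deconvolve(agg, agg, ctx["sbar"], tol=config.tol)
        ctx["deconvolved"][name] = dp
        io.write_deconvolved(dp, out / f"deconvolved_{name}.tsv")
        written.append(f"deconvolved_{name}.tsv")
        summary[name] = profile_stats(dp, smooth_bp=config.smoothing_bp)
    io.write_json(summary, out / "deconvolve_summary.json")
    written.append("deconvolve_summary.json")
    return written


def _stage_mixture(config: RunConfig, ctx: dict, out: Path) -> list:
    dec = ctx["deconvolved"]
    P = normalize_area(np.clip(dec["RPA_DSB"].b_crick, 0, None))
    D = normalize_area(np.clip(dec["DMC1"].b_crick, 0, None))
    R = normalize_area(np.clip(dec["RAD51"].b_crick, 0, None))
    fit = fit_mixture(P, D, R)
    equal = fixed_mixture_fit(P, D, R, (0.5, 0.5))
    io.write_json({
        "alpha": fit.alpha, "beta": fit.beta, "gamma": fit.gamma,
        "prop_dmc1": fit.prop_dmc1, "prop_rad51": fit.prop_rad51,
        "residual_sse": fit.residual_sse,
        "equal_weights_residual_sse": equal["residual_sse"],
    }, out / "mixture.json")
    return ["mixture.json"]


def _stage_skew(config: RunConfig, ctx: dict, out: Path) -> list:
    hotspots = ctx["hotspots"]
    profs = ctx["profiles"]["DMC1"]
    centers = hotspots["center"].to_numpy()
    gaps = np.diff(np.sort(centers))
    neighbor = np.full(len(centers), np.inf)
    if len(centers) > 1:
        order = np.argsort(centers)
        nd = np.minimum(np.concatenate([[np.inf], gaps]),
                        np.concatenate([gaps, [np.inf]]))
        neighbor[order] = nd
    res = classify_and_orient(profs, neighbor_distance=neighbor,
                              threshold=config.skew_threshold_bp)
    labels = [c.label for c in res["calls"]]
    table = pd.DataFrame({
        "center": centers,
        "m_bp": [c.m for c in res["calls"]],
        "label": labels,
    })
    table.to_csv(out / "skew.tsv", sep="\t", index=False)
    n_left = labels.count("left")
    n_right = labels.count("right")
    oriented = sum_profiles(res["profiles"])
    io.write_track(oriented.bin_centers(), oriented.total(),
                   out / "skew_oriented_profile.tsv", "coverage")
    io.write_json({
        "n_left": n_left, "n_right": n_right,
        "n_balanced": labels.count("balanced"),
        "fraction_skewed": (n_left + n_right) / max(1, len(labels) - labels.count("excluded")),
        "side_balance_p": side_balance_test(n_left, n_right)
        if n_left + n_right else None,
    }, out / "skew_summary.json")
    return ["skew.tsv", "skew_oriented_profile.tsv", "skew_summary.json"]


def _stage_dloop(config: RunConfig, ctx: dict, out: Path) -> list:
    hotspots = ctx["hotspots"]
    intensity = ctx.get("intensity")
    dsb_proxy = (intensity["intensity_RPA_DSB"].to_numpy()
                 if intensity is not None else hotspots["spo11_count"].to_numpy())
    bins = equal_signal_bins(dsb_proxy, hotspots["centromere_distance"],
                             config.n_bins)
    co_counts = np.bincount(ctx["co"]["hotspot_index"], minlength=len(hotspots))
    rng = _stage_rng(config, "dloop")
    co_frac, co_ci = bin_fractions(bins, co_counts, config.n_bins,
                                   iterations=config.bootstrap_iterations,
                                   seed=rng)
    template = (intensity["intensity_RPA_TEMPLATE"].to_numpy()
                if intensity is not None else None)
    onehot = np.eye(config.n_bins)[bins]
    dsb_per_bin = onehot.T @ dsb_proxy
    co_per_bin = onehot.T @ co_counts
    rates = rescale_crossover_rate(co_per_bin, dsb_per_bin, config.co_share)
    result = {
        "bin_dsb_proxy": dsb_per_bin, "bin_co_counts": co_per_bin,
        "co_fractions": co_frac, "co_fraction_ci": co_ci,
        "co_rate_per_dsb": rates,
    }
    if template is not None:
        rpa_frac, rpa_ci = bin_fractions(bins, template, config.n_bins,
                                         iterations=config.bootstrap_iterations,
                                         seed=rng)
        rpa_per_dsb = (onehot.T @ template) / dsb_per_bin
        est = estimate_lifespans(rates, rpa_per_dsb, config.co_share,
                                 config.sister_fraction)
        result.update(template_rpa_fractions=rpa_frac,
                      template_rpa_ci=rpa_ci,
                      lifespan_ratio=est.ratio, L_co=est.L_co, L_nco=est.L_nco)
        predictors = np.column_stack([
            hotspots["spo11_count"], intensity["intensity_RPA_DSB"],
            intensity["intensity_DMC1"], intensity["intensity_RAD51"],
            intensity["intensity_RPA_TEMPLATE"]])
        names = ["H_d", "P_d", "D_d", "R_d", "P_r"]
        X = standardize_predictors(predictors)
        selected, model = select_features(X, co_counts, names)
        result.update(selected_predictors=selected,
                      model_aic=model.aic,
                      model_params=dict(zip(["const"] + selected,
                                            model.params.tolist())))
    io.write_json(result, out / "dloop.json")
    return ["dloop.json"]


def _stage_tracts(config: RunConfig, ctx: dict, out: Path) -> list:
    co, nco = ctx["co"], ctx["nco"]
    recs = [(r.snp_left, r.snp_right, r.internal_snps)
            for r in co.itertuples()]
    mass, grid, n_clipped = breakpoint_probability_map(
        recs, centers=co["center"].to_numpy())
    binned = rebin_map(mass)
    dsb_rel = deconvolve_single(binned, ctx["sbar"], tol=config.tol)
    containment = tract_containment(np.clip(dsb_rel, 0, None))
    k = np.arange(len(dsb_rel)) - (len(dsb_rel) - 1) // 2
    io.write_track(grid, mass, out / "co_breakpoint_map.tsv", "probability")
    io.write_track(k * BIN_WIDTH, containment,
                   out / "co_tract_containment.tsv", "containment")
    ncos = list(zip(nco["start"], nco["end"]))
    nmap = nco_tract_map(ncos, centers=nco["center"].to_numpy(), s=ctx["sbar"],
                         tol=config.tol)
    nk = np.arange(len(nmap["dsb_relative"])) - (len(nmap["dsb_relative"]) - 1) // 2
    io.write_track(nk * BIN_WIDTH, nmap["dsb_relative"],
                   out / "nco_tract_map.tsv", "mass")
    io.write_json({"n_crossovers": len(co), "n_clipped": n_clipped,
                   "n_ncos": len(nco), "n_nco_excluded": nmap["n_excluded"]},
                  out / "tracts_summary.json")
    return ["co_breakpoint_map.tsv", "co_tract_containment.tsv",
            "nco_tract_map.tsv", "tracts_summary.json"]


def _stage_foci(config: RunConfig, ctx: dict, out: Path) -> list:
    axes, foci = ctx["axes"], ctx["foci"]
    gen = config.generator
    dists = {"RAD51": [], "DMC1": []}
    fractions = {"RAD51": [], "DMC1": []}
    offsets = []
    for cell in sorted(foci["cell_id"].unique()):
        polys = axes_polylines(axes, cell)
        sub = foci[foci["cell_id"] == cell]
        pts = {ch: sub[sub["channel"] == ch][["x_nm", "y_nm"]].to_numpy()
               for ch in ("RAD51", "DMC1")}
        for ch in ("RAD51", "DMC1"):
            if len(pts[ch]):
                dists[ch].append(distances_to_axes(pts[ch], polys))
        pair = pair_cofoci(pts["RAD51"], pts["DMC1"],
                           config.cofocus_threshold_nm)
        fractions["RAD51"].append(pair["fraction_a"])
        fractions["DMC1"].append(pair["fraction_b"])
        offsets.extend(pair["offsets_a"].tolist())
    d_r = np.concatenate(dists["RAD51"])
    d_d = np.concatenate(dists["DMC1"])
    cmp = axis_proximity_compare(d_r, d_d)
    result = {
        "median_axis_distance_rad51": cmp["median_a"],
        "median_axis_distance_dmc1": cmp["median_b"],
        "axis_proximity_t": cmp["t"], "axis_proximity_p": cmp["p"],
        "cofocus_fraction_rad51": float(np.mean(fractions["RAD51"])),
        "cofocus_fraction_dmc1": float(np.mean(fractions["DMC1"])),
        "median_pair_offset_nm": float(np.median(offsets)) if offsets else None,
    }
    try:
        result["offaxis_uniformity"] = offaxis_uniformity(
            d_r, field_extent=gen.field_nm / 2)
    except ValueError as err:
        result["offaxis_uniformity"] = {"error": str(err)}
    io.write_json(result, out / "foci_summary.json")
    return ["foci_summary.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "deconvolve": _stage_deconvolve,
    "mixture": _stage_mixture,
    "skew": _stage_skew,
    "dloop": _stage_dloop,
    "tracts": _stage_tracts,
    "foci": _stage_foci,
}
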