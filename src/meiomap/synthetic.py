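"""Synthetic hotspot catalogs, strand coverage, repair outcomes and focus
geometry with the statistical structure the downstream analyses assume.

The generator emulates the data layers of a hybrid-mouse meiotic
recombination study at desk scale: hotspot centers with per-homolog read
fractions, SPO11-oligo DSB offsets, strand-polar protein coverage built by
convolving binding kernels with each hotspot's DSB-offset distribution
(Poisson read noise per bin), SNP-censored crossover/non-crossover
outcomes with a centromere-telomere crossover gradient, and paired
RAD51/DMC1 foci along chromosome-axis polylines.

Everything is driven by a single :class:`GeneratorConfig`; identical config
and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import OffsetDistribution, bin_offsets
from .binstats import BIN_WIDTH
from .kernels import BindingKernel, default_kernel
from .profiles import StrandProfile

OFFSET_HALF_BINS = 50  # DSB offsets live within ±1000 bp of the center


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class OffsetModel:
    """Mixture model for DSB positions relative to the hotspot center.

    A central Gaussian component (sd in bp; sd=0 is a point mass) plus
    optional flanking components ``(weight, center, sd)``; all components
    truncated to ``bounds``.
    """

    sd: float = 150.0
    center: float = 0.0
    flanks: tuple = ()
    bounds: tuple = (-1000.0, 1000.0)

    def components(self):
        w_flank = sum(w for w, _, _ in self.flanks)
        if w_flank > 1.0 + 1e-12:
            raise ConfigError("dsb_offset_model: flank weights exceed 1")
        return [(1.0 - w_flank, self.center, self.sd)] + list(self.flanks)

    def _component_cdf(self, x, center, sd):
        lo, hi = self.bounds
        x = np.asarray(x, dtype=float)
        if sd == 0:
            return (x > center).astype(float)
        a, b = (lo - center) / sd, (hi - center) / sd
        return stats.truncnorm.cdf(x, a, b, loc=center, scale=sd)

    def binned_density(self, m: int = OFFSET_HALF_BINS,
                       bin_width: int = BIN_WIDTH) -> np.ndarray:
        """Probability mass per lower-closed 20-bp bin, bins -m..m."""
        edges = (np.arange(-m, m + 2) - 0.5) * bin_width
        dens = np.zeros(2 * m + 1)
        for w, c, sd in self.components():
            if sd == 0:
                idx = int(np.floor(c / bin_width + 0.5))
                if abs(idx) <= m:
                    dens[idx + m] += w
            else:
                dens += w * np.diff(self._component_cdf(edges, c, sd))
        total = dens.sum()
        if total <= 0:
            raise ConfigError("dsb_offset_model: no mass within the bin range")
        return dens / total

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comps = self.components()
        weights = np.array([w for w, _, _ in comps])
        choice = rng.choice(len(comps), size=n, p=weights / weights.sum())
        out = np.empty(n)
        lo, hi = self.bounds
        for i, (_, c, sd) in enumerate(comps):
            sel = choice == i
            k = int(sel.sum())
            if k == 0:
                continue
            if sd == 0:
                out[sel] = c
            else:
                a, b = (lo - c) / sd, (hi - c) / sd
                u = rng.uniform(size=k)
                out[sel] = stats.truncnorm.ppf(u, a, b, loc=c, scale=sd)
        return out


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    n_hotspots: int = 2000
    chrom: str = "chrS"
    chrom_length: int = 120_000_000
    min_separation: int = 8000           # hotspot spacing floor (bp)
    dsb_offset_model: OffsetModel = field(default_factory=OffsetModel)
    kernel_dmc1: BindingKernel | None = None
    kernel_rad51: BindingKernel | None = None
    kernel_rpa_template: BindingKernel | None = None
    rpa_dsb_mix: tuple = (0.65, 0.35)    # DMC1, RAD51 shares of DSB-side RPA
    read_depth: float = 100.0            # expected ChIP reads per hotspot
    spo11_depth: float = 100.0           # expected SPO11 oligos per hotspot
    read_background: float = 0.0         # expected background reads per bin
    overdispersion: float = 0.0          # extra-Poisson variance multiplier
    skew_fraction: float = 0.40          # share of hotspots with side imbalance
    skew_factor: float = 3.0             # more-bound/less-bound mass ratio
    asym_fraction: float = 0.5           # share with f >= 0.9 or f <= 0.1
    co_base_rate: float = 0.10           # mean crossover probability per DSB
    co_gradient: float = 4.0             # telomeric/centromeric rate multiplier
    lifespan_ratio: float = 2.6          # L_co / L_nco used for template RPA
    co_tract_shape: float = 2.0
    co_tract_scale: float = 250.0        # gamma tract length, mean 500 bp
    nco_tract_shape: float = 1.5
    nco_tract_scale: float = 100.0       # gamma tract length, mean 150 bp
    snp_spacing: float = 150.0           # mean bp between SNPs
    informative_fraction: float = 0.5    # SNPs usable for haplotyping
    outcome_events_per_hotspot: float = 5.0
    alleles: tuple = ("CAST", "HUM")
    allele_probs: tuple = (0.6, 0.4)
    # focus geometry (nm)
    n_cells: int = 10
    pairs_per_cell: int = 100
    n_axes_per_cell: int = 5
    axis_step_nm: float = 900.0
    axis_n_vertices: int = 12
    straight_axes: bool = False
    field_nm: float = 12000.0
    focus_axis_sd_rad51: float = 89.0    # half-normal median 60 nm
    focus_axis_sd_dmc1: float = 178.0    # half-normal median 120 nm
    pair_tangent_sd: float = 80.0
    background_fraction_rad51: float = 0.19
    background_fraction_dmc1: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_hotspots < 1:
            raise ConfigError("n_hotspots must be >= 1")
        if self.n_hotspots * self.min_separation * 2 > self.chrom_length:
            raise ConfigError("chrom_length too small for n_hotspots at the "
                              "minimum separation")
        mix = np.asarray(self.rpa_dsb_mix, dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-12:
            raise ConfigError("rpa_dsb_mix weights must be nonnegative and sum to 1")
        if self.read_depth < 0:
            raise ConfigError("read_depth must be nonnegative")
        if self.spo11_depth < 0:
            raise ConfigError("spo11_depth must be nonnegative")
        for name in ("skew_fraction", "asym_fraction", "informative_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.snp_spacing <= 0:
            raise ConfigError("snp_spacing must be positive")
        if self.co_base_rate < 0 or self.co_base_rate > 1:
            raise ConfigError("co_base_rate must be a probability")
        if self.co_gradient <= 0:
            raise ConfigError("co_gradient must be positive")
        for name in ("kernel_dmc1", "kernel_rad51", "kernel_rpa_template"):
            k = getattr(self, name)
            if k is not None:
                try:
                    k.validate()
                except ValueError as err:
                    raise ConfigError(f"{name}: {err}") from err
        self.dsb_offset_model.components()

    def kernel(self, which: str) -> BindingKernel:
        attr = {"DMC1": "kernel_dmc1", "RAD51": "kernel_rad51",
                "RPA_TEMPLATE": "kernel_rpa_template"}[which.upper()]
        k = getattr(self, attr)
        return k if k is not None else default_kernel(which)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _place_centers(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform hotspot centers with a hard minimum separation.

    Draw on a shrunk interval, sort, then re-insert one separation per gap;
    equivalent in law to rejection sampling of the uniform order statistics
    conditioned on all gaps >= min_separation.
    """
    n, sep = config.n_hotspots, config.min_separation
    margin = 10_000
    free = config.chrom_length - 2 * margin - (n - 1) * sep
    raw = np.sort(rng.uniform(0, free, size=n))
    return (margin + raw + sep * np.arange(n)).astype(int)


def simulate_hotspots(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Hotspot catalog plus per-hotspot SPO11-oligo offset samples.

    Returns ``(hotspots, offsets)``: a DataFrame with one row per hotspot
    (center, allele, homolog fraction f, SPO11 count, centromere distance,
    skew annotation, per-hotspot crossover rate) and a list of signed-bp
    offset arrays.  Mouse chromosomes are acrocentric, so the centromere
    distance is the coordinate itself.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    n = config.n_hotspots
    centers = _place_centers(config, rng)

    is_asym = rng.uniform(size=n) < config.asym_fraction
    side = rng.uniform(size=n) < 0.5
    f = np.where(side, 0.1 * rng.uniform(size=n), 1.0 - 0.1 * rng.uniform(size=n))
    f_sym = 0.1 + 0.8 * rng.beta(2.0, 2.0, size=n)
    f = np.where(is_asym, f, f_sym)

    skewed = rng.uniform(size=n) < config.skew_fraction
    skew_side = np.where(rng.uniform(size=n) < 0.5, -1, 1)

    x = centers / config.chrom_length
    g = config.co_gradient
    gradient = (1.0 + (g - 1.0) * x) * 2.0 / (1.0 + g)
    co_rate = np.clip(config.co_base_rate * gradient, 0.0, 1.0)

    n_oligos = rng.poisson(config.spo11_depth, size=n)
    offsets = [config.dsb_offset_model.sample(int(k), rng) for k in n_oligos]

    hotspots = pd.DataFrame({
        "chrom": config.chrom,
        "center": centers,
        "allele": rng.choice(config.alleles, size=n, p=config.allele_probs),
        "f": f,
        "spo11_count": n_oligos,
        "centromere_distance": centers.astype(float),
        "skewed": skewed,
        "skew_side": np.where(skewed, skew_side, 0),
        "co_rate": co_rate,
    })
    return hotspots, offsets


def pooled_offset_distribution(offsets, m: int = OFFSET_HALF_BINS) -> OffsetDistribution:
    """Bin all hotspots' SPO11 offsets together (the solver's s-bar)."""
    return bin_offsets(np.concatenate([np.asarray(o) for o in offsets]), m)


def _strand_weights(skewed: bool, skew_side: int, factor: float) -> tuple:
    if not skewed:
        return 1.0, 1.0
    # more-bound side gets factor x the mass of the less-bound side,
    # total conserved: right-skew boosts Crick (overhang to the right)
    hi = 2.0 * factor / (1.0 + factor)
    lo = 2.0 / (1.0 + factor)
    return (hi, lo) if skew_side > 0 else (lo, hi)


def simulate_coverage(hotspots: pd.DataFrame, kernel: BindingKernel,
                      depth: float, rng: np.random.Generator,
                      offsets=None, offset_model: OffsetModel | None = None,
                      span: int = 6000, noise: bool = True,
                      apply_skew: bool = True, skew_factor: float = 3.0,
                      background: float = 0.0, overdispersion: float = 0.0,
                      depth_scale=None):
    """Strand-specific binned coverage per hotspot.

    Expected Crick coverage is ``depth`` times the kernel convolved with the
    hotspot's DSB-offset distribution (the binned empirical offsets when
    given, else the model density); Watson is its mirror-polarity
    counterpart.  Independent Poisson noise per bin unless ``noise=False``;
    ``overdispersion`` > 0 switches to gamma-Poisson mixing with that extra
    variance multiplier.  ``depth_scale`` optionally multiplies the depth
    per hotspot (e.g. to encode lifespan differences in template-RPA
    signal, or per-homolog shares).
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if background < 0:
        raise ValueError("background must be nonnegative")
    m = span // BIN_WIDTH
    kern = kernel.on_full_grid()
    kern_mir = kern[::-1]  # Watson carries the mirror-polarity kernel
    from .binstats import K_HI, K_LO

    model_density = None if offset_model is None else offset_model.binned_density()
    profiles = []
    for i, row in enumerate(hotspots.itertuples()):
        if offsets is not None and len(offsets[i]) > 0:
            p = bin_offsets(offsets[i], OFFSET_HALF_BINS).normalized()
        elif model_density is not None:
            p = model_density
        else:
            raise ValueError("need per-hotspot offsets or an offset_model")
        d_i = depth if depth_scale is None else depth * float(depth_scale[i])
        # Crick: binding at +k from a DSB at offset l lands at l + k;
        # Watson: overhang polarity points left, so it lands at l - k
        conv_c = np.convolve(p, kern)        # positions -100 .. 175
        conv_w = np.convolve(p, kern_mir)    # positions -175 .. 100
        crick_exp = np.zeros(2 * m + 1)
        watson_exp = np.zeros(2 * m + 1)
        lo_c = m + (-OFFSET_HALF_BINS + K_LO)
        lo_w = m - (OFFSET_HALF_BINS + K_HI)
        crick_exp[lo_c : lo_c + len(conv_c)] = d_i * conv_c
        watson_exp[lo_w : lo_w + len(conv_w)] = d_i * conv_w
        w_c, w_w = 1.0, 1.0
        if apply_skew and getattr(row, "skewed", False):
            w_c, w_w = _strand_weights(True, row.skew_side, skew_factor)
        crick_exp = crick_exp * w_c + background
        watson_exp = watson_exp * w_w + background
        if noise:
            if overdispersion > 0:
                shape = 1.0 / overdispersion
                crick_exp = rng.gamma(shape, crick_exp * overdispersion)
                watson_exp = rng.gamma(shape, watson_exp * overdispersion)
            crick = rng.poisson(crick_exp).astype(float)
            watson = rng.poisson(watson_exp).astype(float)
        else:
            crick, watson = crick_exp, watson_exp
        profiles.append(StrandProfile(crick, watson, BIN_WIDTH,
                                      origin=row.center, chrom=row.chrom))
    return profiles


def simulate_coverage_by_homolog(hotspots, kernel, depth, rng, template: bool = False,
                                 **kwargs):
    """Split coverage between homologs by the hotspot fraction f.

    DSB-side proteins land on the initiating homolog (share f for homolog
    1); ``template=True`` swaps the roles for repair-template binding.
    Returns ``{"hom1": [...], "hom2": [...]}``.
    """
    share1 = hotspots["f"].to_numpy()
    if template:
        share1 = 1.0 - share1
    out = {}
    for label, share in (("hom1", share1), ("hom2", 1.0 - share1)):
        profs = []
        for i, row_share in enumerate(share):
            sub = simulate_coverage(hotspots.iloc[[i]], kernel,
                                    depth * float(row_share), rng,
                                    offsets=None, **kwargs)
            profs.extend(sub)
        out[label] = profs
    return out


def _snp_grid(center: float, rng: np.random.Generator, spacing: float,
              half_span: float = 4000.0) -> np.ndarray:
    n_exp = int(2 * half_span / spacing * 1.5) + 20
    gaps = rng.exponential(spacing, size=n_exp)
    pos = center - half_span + np.cumsum(gaps)
    return pos[pos <= center + half_span]


def simulate_outcomes(hotspots: pd.DataFrame, config: GeneratorConfig,
                      rng: np.random.Generator):
    """SNP-censored crossover and non-crossover records.

    Per hotspot, a Poisson number of repair events is drawn; each event is a
    crossover with the hotspot's per-DSB rate (centromere-telomere gradient
    applied) and otherwise a non-crossover.  The true breakpoint / tract is
    anchored at the event's DSB position and censored by a Poisson-spaced
    SNP grid with an informative subset: crossovers report the flanking
    informative SNPs plus the internal SNPs between them; non-crossovers
    report the minimal converted segment (single position when only one SNP
    converted, undetected when none).
    """
    config.validate()
    co_rows, nco_rows = [], []
    n_undetected = 0
    n_unbounded = 0
    for i, row in enumerate(hotspots.itertuples()):
        n_events = rng.poisson(config.outcome_events_per_hotspot)
        if n_events == 0:
            continue
        snps = _snp_grid(row.center, rng, config.snp_spacing)
        informative = snps[rng.uniform(size=len(snps)) < config.informative_fraction]
        for _ in range(n_events):
            o = float(config.dsb_offset_model.sample(1, rng)[0])
            dsb = row.center + o
            direction = -1.0 if rng.uniform() < 0.5 else 1.0
            if rng.uniform() < row.co_rate:
                t_len = rng.gamma(config.co_tract_shape, config.co_tract_scale)
                bp = dsb + direction * t_len
                left = informative[informative <= bp]
                right = informative[informative > bp]
                if len(left) == 0 or len(right) == 0:
                    n_unbounded += 1
                    continue
                snp_l, snp_r = float(left.max()), float(right.min())
                internal = snps[(snps > snp_l) & (snps < snp_r)]
                co_rows.append({
                    "chrom": row.chrom, "center": row.center,
                    "hotspot_index": i, "snp_left": snp_l, "snp_right": snp_r,
                    "internal_snps": [float(s) for s in internal],
                    "breakpoint_true": float(bp),
                })
            else:
                t_len = rng.gamma(config.nco_tract_shape, config.nco_tract_scale)
                lo, hi = sorted((dsb, dsb + direction * t_len))
                converted = informative[(informative >= lo) & (informative <= hi)]
                if len(converted) == 0:
                    n_undetected += 1
                    continue
                nco_rows.append({
                    "chrom": row.chrom, "center": row.center,
                    "hotspot_index": i,
                    "start": float(converted.min()),
                    "end": float(converted.max()),
                    "n_snps": int(len(converted)),
                })
    co = pd.DataFrame(co_rows, columns=["chrom", "center", "hotspot_index",
                                        "snp_left", "snp_right",
                                        "internal_snps", "breakpoint_true"])
    nco = pd.DataFrame(nco_rows, columns=["chrom", "center", "hotspot_index",
                                          "start", "end", "n_snps"])
    co.attrs["n_unbounded"] = n_unbounded
    nco.attrs["n_undetected"] = n_undetected
    return co, nco


def _random_polyline(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    start = rng.uniform(0, config.field_nm, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    for _ in range(config.axis_n_vertices - 1):
        heading += rng.normal(0, 0.35)
        step = config.axis_step_nm * np.array([np.cos(heading), np.sin(heading)])
        pts.append(np.clip(pts[-1] + step, 0, config.field_nm))
    return np.array(pts)


def simulate_foci(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Axis polylines plus RAD51/DMC1 focus coordinates per cell.

    Paired co-foci sit at a common axis anchor with independent
    perpendicular offsets per channel (half-normal axis distances, RAD51
    closer than DMC1) and a tangential jitter between partners; background
    foci are uniform over the field at the configured per-channel rates.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    axis_rows, focus_rows = [], []
    sds = {"RAD51": config.focus_axis_sd_rad51, "DMC1": config.focus_axis_sd_dmc1}
    bgs = {"RAD51": config.background_fraction_rad51,
           "DMC1": config.background_fraction_dmc1}
    for cell in range(config.n_cells):
        if config.straight_axes:
            polylines = [np.array([[0.0, config.field_nm / 2],
                                   [config.field_nm, config.field_nm / 2]])]
        else:
            polylines = [_random_polyline(config, rng)
                         for _ in range(config.n_axes_per_cell)]
        for a_id, poly in enumerate(polylines):
            for v, (x, y) in enumerate(poly):
                axis_rows.append({"cell_id": cell, "axis_id": a_id,
                                  "vertex": v, "x_nm": x, "y_nm": y})
        seg_starts = np.concatenate([p[:-1] for p in polylines])
        seg_ends = np.concatenate([p[1:] for p in polylines])
        seg_vec = seg_ends - seg_starts
        seg_len = np.linalg.norm(seg_vec, axis=1)
        usable = seg_len > 0
        seg_starts, seg_vec, seg_len = (seg_starts[usable], seg_vec[usable],
                                        seg_len[usable])
        p_seg = seg_len / seg_len.sum()
        for _ in range(config.pairs_per_cell):
            s = rng.choice(len(seg_len), p=p_seg)
            t = rng.uniform()
            anchor = seg_starts[s] + t * seg_vec[s]
            tangent = seg_vec[s] / seg_len[s]
            perp = np.array([-tangent[1], tangent[0]])
            for channel in ("DMC1", "RAD51"):
                d = rng.normal(0, sds[channel]) if sds[channel] > 0 else 0.0
                tau = (rng.normal(0, config.pair_tangent_sd)
                       if channel == "RAD51" and config.pair_tangent_sd > 0 else 0.0)
                pos = anchor + perp * d + tangent * tau
                focus_rows.append({"cell_id": cell, "channel": channel,
                                   "x_nm": pos[0], "y_nm": pos[1],
                                   "background": False})
        for channel in ("DMC1", "RAD51"):
            frac = bgs[channel]
            if frac > 0:
                n_bg = rng.poisson(config.pairs_per_cell * frac / (1 - frac))
                for _ in range(n_bg):
                    x, y = rng.uniform(0, config.field_nm, size=2)
                    focus_rows.append({"cell_id": cell, "channel": channel,
                                       "x_nm": x, "y_nm": y, "background": True})
    axes = pd.DataFrame(axis_rows, columns=["cell_id", "axis_id", "vertex",
                                            "x_nm", "y_nm"])
    foci = pd.DataFrame(focus_rows, columns=["cell_id", "channel", "x_nm",
                                             "y_nm", "background"])
    return axes, foci


def axes_polylines(axes: pd.DataFrame, cell_id) -> list:
    """Extract a cell's axis polylines as a list of (n, 2) arrays."""
    sel = axes[axes["cell_id"] == cell_id]
    return [grp.sort_values("vertex")[["x_nm", "y_nm"]].to_numpy()
            for _, grp in sel.groupby("axis_id")]
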