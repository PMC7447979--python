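# Methods

This note records the models implemented in `meiomap`, the parameter
choices behind the synthetic-data generator, the numerical conventions,
and what the passing tests do and do not establish about real data.

## Coordinate and binning conventions

All coverage and binding profiles live on 20-bp bins centered on the
hotspot (PRDM9-motif midpoint): bin `l` covers `[20(l−½), 20(l+½))` bp,
lower-closed. File intervals are 0-based half-open (BED). DSB-relative
binding profiles are estimated on `k ∈ {−50..125}` (−1000..+2500 bp) and
assumed zero elsewhere; positive `k` has the polarity of the 3′ ssDNA
overhang, so on the Crick strand it points right of the break and on the
Watson strand left. Profile summaries (mode, median, central 95%) clip
negative regularization artifacts to zero, take the mode as the midpoint
of the maximal bin (ties resolve toward the break), and interpolate
quantiles linearly within bins. The half-signal point used for skew calls
is the position of the first bin at which the running cumulative reaches
half the ±5 kb total; this discrete rule makes a symmetric profile yield
exactly the center (an edge-interpolated variant is available via a flag).

## Deconvolution

The expected Crick coverage at bin `j` is `c_j = Σ_k s_{j−k} b_k` with `s`
the binned SPO11-oligo offsets — a Toeplitz system inverted by
least squares using a pseudoinverse in which singular values below
`tol × σ_max` are discarded (`tol = 0.2` by default, the same semantics as
the `tol` argument of R's `MASS::ginv`). The Watson strand is reflected
(`x → −x`, offsets mirrored with it) into Crick polarity and solved
separately; both solutions and their average are returned. Strand
background is estimated per strand as the mean coverage 4000–5000 bp on
the flank away from the signal (left for Crick, right for Watson) and
subtracted with negatives clamped to zero before solving.

The tol-0.2 truncation is a deliberate bias–variance trade: it suppresses
noise amplification but smooths the solution, and the smoothing is not
negligible. A noise-free forward simulation shows that a latent binding
density whose own mode is at 80 bp deconvolves, at tol 0.2 under a
150-bp-sd DSB-offset distribution, to a profile with mode ≈140 bp.
Published binding summaries are statistics of tol-0.2-deconvolved
profiles, so the generator's default kernels are calibrated *through* that
measurement operator (below), and solver exactness is verified separately:
with `tol → 0` and a full-column-rank transform, forward convolution
followed by the solve recovers any supported profile to 1e-6.

## Synthetic-data generator

The generator emulates, at desk scale, the data layers of a hybrid-mouse
SSDS study. Its defaults are the study conditions used throughout the
tests and the acceptance script.

**Hotspots.** 2,000 hotspots on a 120-Mb chromosome, uniformly placed with
a hard ≥8 kb separation (the inclusion rule for skew summaries). Mouse
chromosomes are acrocentric, so centromere distance equals the
coordinate. Homolog fractions `f`: a configurable share (default 50%) of
hotspots are asymmetric (`f` uniform in [0.9, 1] or [0, 0.1]); the rest
draw `f` from a symmetric Beta rescaled into (0.1, 0.9).

**DSB offsets.** A truncated Gaussian (sd 150 bp, bounds ±1 kb) around the
motif midpoint, with optional flanking mixture components; SPO11-oligo
counts per hotspot are Poisson with mean 100.

**Binding kernels.** Unit-area densities on the `k` grid:

* DMC1 — two-component gamma mixture: a sharp near-break component plus a
  broad distal tail. A single gamma matching both the 80-bp mode and
  420-bp median is nearly flat at its mode, unlike the observed sharply
  peaked profile, and makes the binned mode unstable.
* RAD51 — reflected gamma (long tail toward the break). A mode (860 bp)
  above the median (800 bp) is impossible for any gamma, so the reflected
  family is required.
* Repair-template RPA — two-sigma Gaussian peaked at the DMC1 peak
  position, putting roughly 2:1 of its mass on the overhang side of the
  break.

Family parameters are solved deterministically so that the *measured*
summaries — noise-free forward convolution with the standard offset
density, tol-0.2 solve, 100-bp smoothing — reproduce the published values
exactly (DMC1 mode 80/median 420 bp; RAD51 mode 860/median 800 bp;
template-RPA central 95% −560..+740 bp). The kernels' latent summaries
differ slightly from the measured ones; that gap is the regularization
bias discussed above, and both views are exposed
(`BindingKernel.stats()` vs `.measured_stats()`).

**Coverage.** Expected Crick coverage is depth × (kernel ⊛ the hotspot's
empirical DSB-offset distribution); Watson follows the mirror-polarity
model `w_j = Σ_l s_l b_{l−j}`. Read noise is independent Poisson per bin
(depth 100/hotspot by default); overdispersion is available as a
gamma-Poisson knob but defaults to zero because per-bin SSDS noise has no
published characterization. Skewed hotspots (fraction 0.40, as observed)
multiply the more-bound side's mass by a factor (default 3) and the other
side by its reciprocal complement, conserving the total; the skew side is
random and independent of strand, so the left/right balance test is null
by construction. Repair-template RPA depth is additionally scaled per
hotspot by the normalized lifespan mix `c·L_co + (1−c)·L_nco`, which is
what makes lifespan inference from the synthetic data a genuine recovery
problem.

**Outcomes.** Each hotspot receives a Poisson number of repair events
(mean 5). The per-DSB crossover probability averages 0.10 and rises
linearly ~4-fold from centromere to telomere (matching the observed
per-DSB rate range of ~0.04–0.16 across equal-signal bins). Crossover
breakpoints sit a gamma-distributed tract length (shape 2, scale 250 bp;
mean 500 bp, D-loop-sized) from the event's DSB in a random direction and
are censored to the flanking informative SNPs of a Poisson-spaced SNP grid
(mean spacing 150 bp, as in a B6×CAST hybrid; half the SNPs informative).
Non-crossover tracts are shorter (gamma mean 150 bp); the minimal observed
segment spans the converted informative SNPs, single-SNP conversions are
single positions, and tracts containing no informative SNP go undetected
(counted).

**Foci.** Chromosome axes are random-heading polylines (or one straight
axis for controlled tests) in a 12-μm field. Paired foci share an axis
anchor: each channel is displaced perpendicular to the axis by a centered
Gaussian whose half-normal medians are 60 nm (RAD51) and 120 nm (DMC1),
plus a tangential jitter between partners; background foci (19% of RAD51,
3% of DMC1) are uniform over the field.

## Downstream analyses

**Intensity.** Background-corrected Crick coverage summed over
[−250, +2000] bp plus Watson over the mirror window (hotspot width 500 bp,
binding width 2000 bp), with the same flank-background rule as the solver;
linear in coverage and never negative. Group elevation (e.g. X vs
autosomes) uses zero-intercept slopes of intensity on SPO11 count, because
signal is proportional to DSB number by construction.

**Mixture.** All three deconvolved profiles are normalized to area 1
before the OLS fit. The default fit uses the strand profiles in Crick
polarity; negative fitted coefficients are reported with a warning and
leave the proportions undefined rather than being constrained away. A
fixed-proportion fit (intercept and common scale free) supports
comparisons such as 50:50 versus the free optimum.

**Skew.** Half-signal point on strand-summed coverage within ±5 kb;
skewed iff >150 bp from the center; right-skewed hotspots are mirrored
(strand swap + reflection) so all skewed hotspots have excess signal on
the left, and the same orientation is applied to linked per-hotspot tracks.
The left-vs-right count is tested with the exact two-sided binomial
(minimum-likelihood convention).

**Crossovers and lifespans.** Hotspots sorted by centromere distance are
split at cumulative DSB-proxy quantiles into four equal-signal bins;
per-bin event fractions get bootstrap CIs from resampling hotspots (the
sampling unit) with replacement across the full set, 100,000 iterations by
default. Raw per-bin CO/DSB ratios are rescaled by one constant so the
weighted mean is 10% (the assumed average crossover resolution rate), then
the lifespan system is solved with equal bin weights. Sister repair enters
as `R_b = c_b·L_co + ((1−s) − c_b)·L_nco`: sister events consume DSBs
without contributing template RPA, which reproduces the expected ordering
(the estimated ratio declines as the assumed sister fraction rises). Note
the 4-bin system is conditioned on a narrow crossover-rate range, so a
single draw at 1% multiplicative noise carries ~6% spread in the ratio;
the estimator is unbiased and its accuracy is assessed over replicates.
The crossover feature regression standardizes all eight binding measures
to mean 0/variance 1, fits OLS, and searches bidirectionally from the full
model for the AIC-minimal subset. AIC retains any given pure-noise
predictor with probability ≈0.16 by construction; the tests assert that
behavior rather than an unattainable always-exact selection.

**Tracts.** Each crossover contributes total mass 1, split equally across
the inter-SNP intervals between its two informative SNPs and uniform per
bp within each interval (the alternative — uniform across the whole
censored region — is available via a flag). The aggregate ±2 kb per-bp map
is rebinned to 20 bp and deconvolved with the single-track solver.
Containment assumes every conversion tract overlaps its DSB (supported by
tetrad data, 11/12 ≈ 92%; surfaced here as an assumption):
`containment(x) = Σ_{d : x between 0 and d} mass(d)`, so containment at
the break equals the total mass. Non-crossovers contribute equal mass
regardless of length over their minimal converted segment, smoothed with a
100-bp moving window before deconvolution.

**Foci.** Distances are exact point-to-segment minima over axis polylines
(rigid-motion invariant); co-foci use per-focus nearest neighbors across
channels at 300 nm (not mutual-nearest matching); axis proximity uses
medians plus Welch's t; far-off-axis distances (>450 nm) are tested
against uniform on (cutoff, field extent] by one-sample KS. With curved,
dense axes, genuine signal foci also reach the far field, so the uniformity
test rejects on full simulations; it calibrates (rarely rejects) on
background-only data with a straight axis, which is the regime the test is
meant for.

## Problem sizes and runtime

The standard experiments use 2,000 hotspots at depth 100 (400k reads per
track), matching the asymmetric-hotspot set sizes of the real study within
a factor of two; recovery experiments run in seconds and the whole test
suite in well under a minute of compute. Bootstrap CIs default to 100,000
iterations in the library; the analysis drivers use 20,000, which changes
CI endpoints by well under the CI width.

## What the tests do and do not show

Passing recovery tests show that the estimators invert the generator's
forward model at realistic noise levels — unbiased mixture proportions to
±2 points, profile modes to one bin, lifespan ratios to a few percent.
They do not certify behavior under features the generator omits: mappability
and ITR-detection artifacts, locally varying background, PRDM9-motif
heterogeneity within hotspots, overdispersed or correlated read noise
(available as a knob but off by default), non-uniform SNP ascertainment,
or image-segmentation errors upstream of focus coordinates. The
deconvolution bias analysis applies to the default tol and offset spread;
sharper empirical DSB distributions are better conditioned and less
biased.
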