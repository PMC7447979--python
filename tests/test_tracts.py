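"""Breakpoint probability maps, single-track deconvolution and tract
containment."""

import numpy as np
import pytest

from meiomap.deconvolution import OffsetDistribution, bin_offsets
from meiomap.tracts import (breakpoint_probability_map, deconvolve_single,
                            nco_tract_map, rebin_map, tract_containment)


def containment_oracle(bp_mass, k_lo):
    """Brute-force enumeration over (breakpoint, position) pairs."""
    n = len(bp_mass)
    out = np.zeros(n)
    for i, mass in enumerate(bp_mass):
        d = i + k_lo
        for j in range(n):
            x = j + k_lo
            if min(0, d) <= x <= max(0, d):
                out[j] += mass
    return out


class TestBreakpointMap:
    def test_inter_snp_intervals_get_equal_mass(self):
        # informative SNPs at -400/+600, internal SNPs at 0 and +200
        mass, grid, _ = breakpoint_probability_map([(-400, 600, [0, 200])])
        seg1 = mass[(grid >= -400) & (grid < 0)].sum()
        seg2 = mass[(grid >= 0) & (grid < 200)].sum()
        seg3 = mass[(grid >= 200) & (grid < 600)].sum()
        assert seg1 == pytest.approx(1 / 3)
        assert seg2 == pytest.approx(1 / 3)
        assert seg3 == pytest.approx(1 / 3)
        # uniform per bp within each interval
        inner = mass[(grid >= -400) & (grid < 0)]
        assert np.ptp(inner) == pytest.approx(0.0, abs=1e-15)

    def test_no_internal_snps_uniform_over_interval(self):
        mass, grid, _ = breakpoint_probability_map([(-100, 100, [])])
        sel = (grid >= -100) & (grid < 100)
        assert mass[sel].sum() == pytest.approx(1.0)
        assert np.all(mass[~sel] == 0)

    def test_two_identical_crossovers_double_the_map(self):
        rec = (-150, 250, [50])
        m1, _, _ = breakpoint_probability_map([rec])
        m2, _, _ = breakpoint_probability_map([rec, rec])
        np.testing.assert_allclose(m2, 2 * m1)

    def test_mass_conservation(self, rng):
        recs = []
        for _ in range(30):
            l = rng.uniform(-1500, -50)
            r = rng.uniform(50, 1500)
            internal = np.sort(rng.uniform(l, r, size=rng.integers(0, 4)))
            recs.append((l, r, internal.tolist()))
        mass, _, _ = breakpoint_probability_map(recs)
        assert mass.sum() == pytest.approx(len(recs), rel=1e-9)

    def test_whole_interval_reading(self):
        mass, grid, _ = breakpoint_probability_map([(-400, 600, [0, 200])],
                                                   per_interval=False)
        sel = (grid >= -400) & (grid < 600)
        assert np.ptp(mass[sel]) == pytest.approx(0.0, abs=1e-15)


class TestDeconvolveSingle:
    def test_point_mass_offsets_identity(self):
        s = bin_offsets(np.zeros(50), m=50)
        track = np.zeros(201)  # ±2000 bp in 20-bp bins
        track[100 + 10] = 5.0
        out = deconvolve_single(track, s, tol=1e-10)
        assert out[10 + 50] == pytest.approx(5.0 / 50.0, abs=1e-8)

    def test_forward_oracle_recovery(self):
        from test_deconvolution import forward_coverage

        b_true = np.zeros(176)
        b_true[50:70] = np.linspace(1, 0, 20)
        counts = np.zeros(101)
        counts[50], counts[53] = 3.0, 1.0
        s = OffsetDistribution(counts)
        cov = forward_coverage(b_true, s, m_cov=150)
        out = deconvolve_single(cov, s, tol=1e-8)
        assert np.max(np.abs(out - b_true)) <= 1e-6

    def test_all_zero_map(self):
        s = bin_offsets(np.zeros(10), m=50)
        out = deconvolve_single(np.zeros(201), s)
        assert np.all(out == 0)


class TestTractContainment:
    def test_single_breakpoint(self):
        mass = np.zeros(101)  # k in -50..50, 20-bp bins
        mass[50 + 25] = 1.0   # breakpoint at +500
        cont = tract_containment(mass)
        k = np.arange(-50, 51)
        assert np.all(cont[(k >= 0) & (k <= 25)] == 1.0)
        assert cont[50 + 30] == 0.0
        assert cont[50 - 5] == 0.0

    def test_two_sided_masses(self):
        mass = np.zeros(101)
        mass[50 + 25] = 0.6   # +500
        mass[50 - 15] = 0.4   # -300
        cont = tract_containment(mass)
        assert cont[50 + 10] == pytest.approx(0.6)   # +200
        assert cont[50 - 5] == pytest.approx(0.4)    # -100
        assert cont[50 + 30] == 0.0                  # +600
        assert cont[50] == pytest.approx(1.0)        # the DSB is in every tract

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            mass = rng.uniform(size=41) * (rng.uniform(size=41) < 0.4)
            got = tract_containment(mass, k_lo=-20)
            np.testing.assert_allclose(got, containment_oracle(mass, -20))

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            tract_containment(np.array([-1.0, 0.0, 1.0]))


class TestNcoTractMap:
    def test_single_snp_conversion_is_point_mass(self):
        out = nco_tract_map([(100.0, 100.0)], smooth_bp=0)
        grid = out["grid"]
        assert out["raw_bp"][grid == 100][0] == pytest.approx(1.0)
        assert out["raw_bp"].sum() == pytest.approx(1.0)

    def test_multi_snp_uniform_between_furthest(self):
        out = nco_tract_map([(100.0, 250.0)], smooth_bp=0)
        grid = out["grid"]
        sel = (grid >= 100) & (grid < 250)
        assert np.ptp(out["raw_bp"][sel]) == pytest.approx(0.0, abs=1e-15)
        assert out["raw_bp"][sel].sum() == pytest.approx(1.0)

    def test_equal_weight_regardless_of_length(self):
        short = nco_tract_map([(0.0, 50.0)], smooth_bp=0)["raw_bp"].sum()
        long = nco_tract_map([(-900.0, 900.0)], smooth_bp=0)["raw_bp"].sum()
        assert short == pytest.approx(1.0, rel=1e-9)
        assert long == pytest.approx(1.0, rel=1e-9)
        both = nco_tract_map([(0.0, 50.0), (-900.0, 900.0)], smooth_bp=0)
        assert both["raw_bp"].sum() == pytest.approx(2.0, rel=1e-9)

    def test_distant_nco_excluded_and_counted(self):
        out = nco_tract_map([(5000.0, 5100.0), (0.0, 0.0)], smooth_bp=0)
        assert out["n_excluded"] == 1
        assert out["raw_bp"].sum() == pytest.approx(1.0)

    def test_smoothing_and_deconvolution_path(self):
        s = bin_offsets(np.zeros(100), m=50)
        out = nco_tract_map([(0.0, 200.0), (-100.0, -100.0)], s=s)
        assert "dsb_relative" in out
        assert out["map_bp"].sum() == pytest.approx(2.0, rel=1e-6)


class TestSnpSpacingLimit:
    def test_breakpoint_map_converges_with_snp_density(self):
        """As SNP spacing shrinks the censored map approaches the true
        breakpoint density (L1 distance decreasing)."""
        from meiomap.synthetic import GeneratorConfig, simulate_hotspots, simulate_outcomes

        l1 = []
        for spacing in (400.0, 100.0, 25.0):
            cfg = GeneratorConfig(n_hotspots=150, snp_spacing=spacing,
                                  informative_fraction=1.0, co_base_rate=0.8,
                                  co_gradient=1.0, outcome_events_per_hotspot=4.0,
                                  seed=2)
            rng = cfg.rng()
            hotspots, _ = simulate_hotspots(cfg, rng)
            co, _ = simulate_outcomes(hotspots, cfg, rng)
            recs = [(r.snp_left - r.center, r.snp_right - r.center,
                     [s - r.center for s in r.internal_snps])
                    for r in co.itertuples()]
            mass, grid, _ = breakpoint_probability_map(recs)
            true_bp = (co["breakpoint_true"] - co["center"]).to_numpy()
            truth = np.zeros_like(mass)
            inside = np.abs(true_bp) <= 2000
            idx = np.round(true_bp[inside]).astype(int) + 2000
            np.add.at(truth, idx, 1.0)
            # compare at 100-bp resolution
            mb = rebin_map(mass, bin_width=100)
            tb = rebin_map(truth, bin_width=100)
            l1.append(np.abs(mb / mb.sum() - tb / tb.sum()).sum())
        assert l1[0] > l1[1] > l1[2]
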