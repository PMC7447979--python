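"""Generator behavior: determinism, degenerate limits, forward-model
expectations, outcome censoring."""

import numpy as np
import pandas as pd
import pytest

from meiomap.deconvolution import deconvolve
from meiomap.kernels import default_kernel, point_mass_kernel
from meiomap.profiles import sum_profiles
from meiomap.synthetic import (ConfigError, GeneratorConfig, OffsetModel,
                               pooled_offset_distribution, simulate_coverage,
                               simulate_foci, simulate_hotspots,
                               simulate_outcomes)


class TestConfigValidation:
    def test_bad_mix_names_field(self):
        cfg = GeneratorConfig(rpa_dsb_mix=(0.7, 0.4))
        with pytest.raises(ConfigError, match="rpa_dsb_mix"):
            cfg.validate()

    def test_bad_hotspot_count(self):
        with pytest.raises(ConfigError, match="n_hotspots"):
            GeneratorConfig(n_hotspots=0).validate()

    def test_chromosome_too_short(self):
        with pytest.raises(ConfigError, match="chrom_length"):
            GeneratorConfig(n_hotspots=1000, chrom_length=10_000_000).validate()

    def test_bad_snp_spacing(self):
        with pytest.raises(ConfigError, match="snp_spacing"):
            GeneratorConfig(snp_spacing=0.0).validate()


class TestSimulateHotspots:
    def test_count_and_seed_determinism(self, small_config):
        h1, o1 = simulate_hotspots(small_config)
        h2, o2 = simulate_hotspots(small_config)
        assert len(h1) == small_config.n_hotspots
        pd.testing.assert_frame_equal(h1, h2)
        for a, b in zip(o1, o2):
            np.testing.assert_array_equal(a, b)

    def test_minimum_separation_enforced(self, small_config):
        h, _ = simulate_hotspots(small_config)
        gaps = np.diff(np.sort(h["center"]))
        assert gaps.min() >= small_config.min_separation

    def test_full_asymmetry(self):
        cfg = GeneratorConfig(n_hotspots=200, asym_fraction=1.0, seed=2)
        h, _ = simulate_hotspots(cfg)
        assert np.all((h["f"] >= 0.9) | (h["f"] <= 0.1))

    def test_point_mass_offsets(self):
        cfg = GeneratorConfig(n_hotspots=20,
                              dsb_offset_model=OffsetModel(sd=0.0), seed=1)
        _, offsets = simulate_hotspots(cfg)
        assert all(np.all(o == 0.0) for o in offsets)


class TestSimulateCoverage:
    def test_zero_depth_gives_zero_coverage(self, small_config):
        h, o = simulate_hotspots(small_config)
        profs = simulate_coverage(h, default_kernel("DMC1"), 0.0,
                                  small_config.rng(), offsets=o)
        assert all(p.crick.sum() == 0 and p.watson.sum() == 0 for p in profs)

    def test_negative_depth_raises(self, small_config):
        h, o = simulate_hotspots(small_config)
        with pytest.raises(ValueError):
            simulate_coverage(h, default_kernel("DMC1"), -1.0,
                              small_config.rng(), offsets=o)

    def test_point_mass_noise_free_equals_depth_times_kernel(self):
        cfg = GeneratorConfig(n_hotspots=3, dsb_offset_model=OffsetModel(sd=0.0),
                              skew_fraction=0.0, seed=4)
        h, o = simulate_hotspots(cfg)
        kern = default_kernel("DMC1")
        profs = simulate_coverage(h, kern, 80.0, cfg.rng(), offsets=o,
                                  noise=False)
        p = profs[0]
        grid = kern.on_full_grid()
        sel = (p.bin_centers() >= -1000) & (p.bin_centers() <= 2500)
        np.testing.assert_allclose(p.crick[sel], 80.0 * grid, atol=1e-9)
        # the Watson strand carries the mirror-polarity coverage
        np.testing.assert_allclose(p.watson, p.crick[::-1], atol=1e-9)

    def test_expected_total_coverage_equals_depth(self):
        # sum over bins of E[coverage] = depth x kernel area = depth
        cfg = GeneratorConfig(n_hotspots=1000, skew_fraction=0.0, seed=6)
        h, o = simulate_hotspots(cfg)
        profs = simulate_coverage(h, default_kernel("DMC1"), 30.0, cfg.rng(),
                                  offsets=o)
        totals = np.array([p.crick.sum() for p in profs])
        se = np.sqrt(30.0 / len(totals))
        assert abs(totals.mean() - 30.0) <= 3 * se

    def test_watson_crick_total_areas_equal_in_expectation(self):
        cfg = GeneratorConfig(n_hotspots=400, skew_fraction=0.0, seed=8)
        h, o = simulate_hotspots(cfg)
        profs = simulate_coverage(h, default_kernel("RAD51"), 50.0, cfg.rng(),
                                  offsets=o)
        agg = sum_profiles(profs)
        assert agg.watson.sum() == pytest.approx(agg.crick.sum(), rel=0.02)

    def test_noise_free_point_mass_roundtrip_recovers_kernel(self):
        """Deconvolution of noise-free coverage from point-mass offsets
        recovers the generating kernel to 1e-6."""
        cfg = GeneratorConfig(n_hotspots=5, dsb_offset_model=OffsetModel(sd=0.0),
                              skew_fraction=0.0, seed=4)
        h, o = simulate_hotspots(cfg)
        kern = default_kernel("RAD51")
        profs = simulate_coverage(h, kern, 100.0, cfg.rng(), offsets=o,
                                  noise=False)
        agg = sum_profiles(profs)
        sbar = pooled_offset_distribution(o)
        dp = deconvolve(agg, agg, sbar, tol=1e-10)
        # the solve divides out the oligo counts: per-DSB binding, i.e. the
        # unit-area kernel itself, times total reads / total oligos
        scale = 100.0 * len(h) / sbar.total()
        truth = scale * kern.on_full_grid()
        assert np.max(np.abs(dp.b_crick - truth)) <= 1e-6 * truth.max()

    def test_seed_determinism(self, small_config):
        h, o = simulate_hotspots(small_config)
        p1 = simulate_coverage(h, default_kernel("DMC1"), 20.0,
                               np.random.default_rng(5), offsets=o)
        p2 = simulate_coverage(h, default_kernel("DMC1"), 20.0,
                               np.random.default_rng(5), offsets=o)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.crick, b.crick)


class TestSimulateOutcomes:
    def test_snp_spacing_limit_shrinks_intervals(self):
        widths = []
        for spacing in (500.0, 50.0, 5.0):
            cfg = GeneratorConfig(n_hotspots=100, snp_spacing=spacing,
                                  informative_fraction=1.0, co_base_rate=0.5,
                                  outcome_events_per_hotspot=3.0, seed=3)
            h, _ = simulate_hotspots(cfg)
            co, _ = simulate_outcomes(h, cfg, cfg.rng())
            widths.append((co["snp_right"] - co["snp_left"]).median())
        assert widths[0] > widths[1] > widths[2]

    def test_reported_interval_brackets_true_breakpoint(self, small_config):
        h, _ = simulate_hotspots(small_config)
        co, _ = simulate_outcomes(h, small_config, small_config.rng())
        if len(co):
            assert np.all(co["snp_left"] <= co["breakpoint_true"])
            assert np.all(co["breakpoint_true"] < co["snp_right"])

    def test_flat_gradient_gives_equal_rates_across_bins(self):
        cfg = GeneratorConfig(n_hotspots=500, co_gradient=1.0,
                              outcome_events_per_hotspot=10.0, seed=10)
        h, _ = simulate_hotspots(cfg)
        co, nco = simulate_outcomes(h, cfg, cfg.rng())
        edges = np.quantile(h["center"], [0, 0.25, 0.5, 0.75, 1.0])
        co_bins = np.clip(np.searchsorted(edges, co["center"]) - 1, 0, 3)
        all_bins = np.clip(np.searchsorted(edges, h["center"]) - 1, 0, 3)
        events_per_bin = np.bincount(all_bins, weights=None, minlength=4) * \
            cfg.outcome_events_per_hotspot
        rates = np.bincount(co_bins, minlength=4) / events_per_bin
        p = rates.mean()
        se = np.sqrt(p * (1 - p) / events_per_bin)
        assert np.all(np.abs(rates - p) < 4 * se)

    def test_single_snp_conversion_is_single_position(self):
        cfg = GeneratorConfig(n_hotspots=200, snp_spacing=2000.0,
                              informative_fraction=1.0, co_base_rate=0.0,
                              nco_tract_scale=50.0,
                              outcome_events_per_hotspot=3.0, seed=12)
        h, _ = simulate_hotspots(cfg)
        _, nco = simulate_outcomes(h, cfg, cfg.rng())
        singles = nco[nco["n_snps"] == 1]
        assert len(singles) > 0
        assert np.all(singles["start"] == singles["end"])


class TestSimulateFoci:
    def test_seed_determinism(self, small_config):
        a1, f1 = simulate_foci(small_config)
        a2, f2 = simulate_foci(small_config)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_background_rate(self):
        cfg = GeneratorConfig(n_cells=6, pairs_per_cell=200,
                              background_fraction_rad51=0.19, seed=14)
        _, foci = simulate_foci(cfg)
        r = foci[foci.channel == "RAD51"]
        frac = r["background"].mean()
        assert frac == pytest.approx(0.19, abs=0.04)
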