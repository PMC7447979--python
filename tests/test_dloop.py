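"""Distance bins, bootstrap fractions, crossover rates, lifespan inference
and the stepwise crossover feature regression."""

import numpy as np
import pytest

from meiomap.dloop import (bin_fractions, crossover_feature_model,
                           equal_signal_bins, estimate_lifespans,
                           rescale_crossover_rate, select_features,
                           standardize_predictors)


class TestEqualSignalBins:
    def test_equal_weights_split_evenly(self):
        bins = equal_signal_bins(np.ones(8), np.arange(8), n_bins=4)
        np.testing.assert_array_equal(bins, [0, 0, 1, 1, 2, 2, 3, 3])

    def test_cumulative_quartile_split(self):
        bins = equal_signal_bins(np.array([3.0, 1.0, 1.0, 3.0]),
                                 np.arange(4), n_bins=4)
        np.testing.assert_array_equal(bins, [0, 1, 2, 3])

    def test_single_bin(self):
        bins = equal_signal_bins(np.ones(5), np.arange(5), n_bins=1)
        assert set(bins) == {0}

    def test_order_follows_key_not_input_order(self):
        key = np.array([3.0, 0.0, 2.0, 1.0])
        bins = equal_signal_bins(np.ones(4), key, n_bins=4)
        np.testing.assert_array_equal(bins, [3, 0, 2, 1])

    def test_heavy_hotspot_warns(self):
        with pytest.warns(UserWarning, match="share"):
            equal_signal_bins(np.array([10.0, 1.0, 1.0, 1.0]), np.arange(4),
                              n_bins=4)

    def test_bin_weights_balanced_within_one_hotspot(self, rng):
        w = rng.uniform(0.5, 2.0, size=200)
        bins = equal_signal_bins(w, rng.uniform(size=200), n_bins=4)
        totals = np.array([w[bins == b].sum() for b in range(4)])
        assert np.all(np.abs(totals - w.sum() / 4) <= w.max())


class TestBinFractions:
    def test_uniform_rate_near_quarter(self, rng):
        bins = np.repeat(np.arange(4), 250)
        events = rng.poisson(5, size=1000)
        frac, ci = bin_fractions(bins, events, iterations=200, seed=1)
        assert frac.sum() == pytest.approx(1.0)
        assert np.all(np.abs(frac - 0.25) < 0.05)

    def test_all_events_in_last_bin(self):
        bins = np.repeat(np.arange(4), 5)
        events = np.where(bins == 3, 2.0, 0.0)
        frac, ci = bin_fractions(bins, events, iterations=100, seed=0)
        np.testing.assert_allclose(frac, [0, 0, 0, 1])
        np.testing.assert_allclose(ci[3], [1.0, 1.0])

    def test_ci_contains_plugin_estimate(self, rng):
        bins = rng.integers(0, 4, size=300)
        events = rng.poisson(3, size=300)
        frac, ci = bin_fractions(bins, events, iterations=1000, seed=5)
        assert np.all(ci[:, 0] <= frac) and np.all(frac <= ci[:, 1])

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            bin_fractions(np.zeros(4, int), np.zeros(4), iterations=10)


class TestRescaleCrossoverRate:
    def test_mean_already_at_target_unchanged(self):
        rates = rescale_crossover_rate(np.array([0.05, 0.10, 0.15, 0.10]),
                                       np.ones(4), mean_rate=0.10)
        np.testing.assert_allclose(rates, [0.05, 0.10, 0.15, 0.10])

    def test_halving_to_target(self):
        rates = rescale_crossover_rate(np.array([0.10, 0.20, 0.30, 0.20]),
                                       np.ones(4), mean_rate=0.10)
        np.testing.assert_allclose(rates, [0.05, 0.10, 0.15, 0.10])

    def test_linear_in_mean_rate(self):
        co, dsb = np.array([1.0, 2.0, 3.0]), np.array([10.0, 10.0, 10.0])
        r10 = rescale_crossover_rate(co, dsb, 0.10)
        r15 = rescale_crossover_rate(co, dsb, 0.15)
        np.testing.assert_allclose(r15, 1.5 * r10)

    def test_between_bin_ratios_preserved(self, rng):
        co = rng.uniform(1, 5, size=4)
        dsb = rng.uniform(50, 100, size=4)
        rates = rescale_crossover_rate(co, dsb, 0.10)
        np.testing.assert_allclose(rates[1:] / rates[0],
                                   (co[1:] / dsb[1:]) / (co[0] / dsb[0]))

    def test_zero_crossovers_raises(self):
        with pytest.raises(ValueError):
            rescale_crossover_rate(np.zeros(4), np.ones(4))


class TestEstimateLifespans:
    def test_closed_form_two_by_two(self):
        est = estimate_lifespans([0.1, 0.2], [1.16, 1.32])
        assert est.L_nco == pytest.approx(1.0, abs=1e-10)
        assert est.L_co == pytest.approx(2.6, abs=1e-10)
        assert est.ratio == pytest.approx(2.6, abs=1e-10)

    def test_identical_rates_singular(self):
        with pytest.raises(ValueError, match="singular"):
            estimate_lifespans([0.1, 0.1, 0.1], [1.0, 1.0, 1.0])

    def test_ratio_scale_invariant(self):
        a = estimate_lifespans([0.05, 0.15], [1.1, 1.3])
        b = estimate_lifespans([0.05, 0.15], [11.0, 13.0])
        assert a.ratio == pytest.approx(b.ratio, rel=1e-12)

    def test_recovery_with_one_percent_noise(self):
        # single 4-bin draws spread ~6%, so accuracy is judged on the mean
        rng = np.random.default_rng(8)
        c = np.array([0.04, 0.08, 0.12, 0.16])
        truth = 2.6
        ratios = []
        for _ in range(50):
            r = (c * truth + (1 - c)) * (1 + 0.01 * rng.standard_normal(4))
            ratios.append(estimate_lifespans(c, r).ratio)
        ratios = np.array(ratios)
        assert np.mean(ratios) == pytest.approx(truth, rel=0.05)
        assert np.all(np.abs(ratios / truth - 1) < 0.25)

    def test_sister_repair_lowers_estimate(self):
        """With sister repair, the same observed rates and template signal
        imply a smaller crossover/non-crossover lifespan gap."""
        c = np.array([0.04, 0.08, 0.12, 0.16])
        r = c * 2.6 + (1 - c)
        ratios = [estimate_lifespans(c, r, sister_fraction=s).ratio
                  for s in (0.0, 0.05, 0.2, 0.5)]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestFeatureModel:
    def make_X(self, rng, n=200, p=8):
        return standardize_predictors(rng.normal(size=(n, p)))

    def test_zero_noise_coefficient_recovered(self, rng):
        X = self.make_X(rng)
        y = 2.0 * X[:, 0]
        names = ["H_d", "H_r", "P_d", "P_r", "D_d", "D_r", "R_d", "R_r"]
        res = crossover_feature_model(X, y, names)
        assert res.params[1] == pytest.approx(2.0, abs=1e-8)

    def test_unstandardized_predictors_rejected(self, rng):
        X = rng.normal(loc=5.0, size=(100, 3))
        with pytest.raises(ValueError, match="standardized"):
            crossover_feature_model(X, X[:, 0])

    def test_collinear_column_dropped_with_warning(self, rng):
        X = self.make_X(rng, p=3)
        X = np.column_stack([X, X[:, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            res = crossover_feature_model(X, X[:, 1], ["a", "b", "c", "a2"])
        assert res.predictor_names == ["a", "b", "c"]

    def test_stepwise_keeps_signal_drops_noise(self):
        # AIC keeps a given noise predictor ~16% of the time by construction,
        # so the check is: signal always retained, noise mostly dropped
        rng = np.random.default_rng(3)
        kept_signal = 0
        noise_kept = 0
        for _ in range(25):
            X = self.make_X(rng, n=150)
            y = 1.5 * X[:, 2] + rng.normal(0, 0.5, size=150)
            selected, _ = select_features(X, y, [f"x{i}" for i in range(8)])
            kept_signal += "x2" in selected
            noise_kept += len(selected) - ("x2" in selected)
        assert kept_signal == 25
        assert noise_kept / (25 * 7) < 0.25  # per-noise-predictor keep rate

    def test_pure_noise_response_selects_few_predictors(self):
        rng = np.random.default_rng(4)
        n_selected = []
        for _ in range(25):
            X = self.make_X(rng, n=150)
            y = rng.normal(size=150)
            selected, _ = select_features(X, y)
            n_selected.append(len(selected))
        # expected ~1.3 of 8 retained under the AIC threshold
        assert np.mean(n_selected) < 3.0
        assert min(n_selected) == 0
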