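import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from aposim import analysis as an
from aposim.fixtures import generate_logistic_outcomes, generate_timeseries_fixture
from conftest import grid_search_logit_mle as _grid_search_mle


class TestClassifier:
    def test_strict_threshold_boundary(self):
        assert an.classify_predation_pressure(799) is True
        assert an.classify_predation_pressure(800) is False
        assert an.classify_predation_pressure(1000) is False

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            an.classify_predation_pressure(-1)


class TestPredatorFilter:
    def test_boundary_inclusive(self):
        df = pd.DataFrame({
            "poison_level": [0.1] * 3, "final_poison_abundance": [500] * 3,
            "under_pressure": [True] * 3, "predator_count_final": [99, 100, 250],
        })
        kept = an.filter_runs_min_predators(df)
        assert kept["predator_count_final"].tolist() == [100, 250]

    def test_empty_and_identity(self):
        df = an.outcomes_to_frame([])
        assert len(an.filter_runs_min_predators(df)) == 0
        full = generate_logistic_outcomes(-5, 22, n_per_level=5, seed=0,
                                          predator_range=(100, 200))
        assert len(an.filter_runs_min_predators(full)) == len(full)




class TestAvoidanceLogit:
    def test_matches_grid_search_mle_on_small_dataset(self):
        levels = np.array([0.1] * 10 + [0.4] * 10)
        y = np.array([0, 0, 0, 0, 0, 0, 0, 1, 1, 1] + [1, 1, 1, 1, 1, 1, 1, 0, 0, 1])
        df = pd.DataFrame({
            "poison_level": levels, "final_poison_abundance": np.where(y, 950, 400),
            "under_pressure": y == 0, "predator_count_final": 200,
        })
        res = an.fit_avoidance_logistic(df)
        b0, b1 = _grid_search_mle(levels, y)
        assert res.params[0] == pytest.approx(b0, abs=1e-3)
        assert res.params[1] == pytest.approx(b1, abs=1e-3)

    def test_matches_grid_search_on_random_datasets(self):
        rng = np.random.default_rng(123)
        for _ in range(3):
            levels = np.repeat([0.05, 0.2, 0.5], 12)
            y = (rng.random(36) < expit(-2 + 8 * levels)).astype(int)
            if len(np.unique(y)) < 2 or an._separation(levels, y):
                continue
            df = pd.DataFrame({
                "poison_level": levels,
                "final_poison_abundance": np.where(y, 950, 400),
                "under_pressure": y == 0, "predator_count_final": 150,
            })
            res = an.fit_avoidance_logistic(df)
            b0, b1 = _grid_search_mle(levels, y)
            assert res.params[0] == pytest.approx(b0, abs=1e-3)
            assert res.params[1] == pytest.approx(b1, abs=1e-3)

    def test_internal_irls_agrees_with_statsmodels(self):
        # the fast bootstrap refitter must match the statsmodels GLM headline
        # fit to near machine precision
        rng = np.random.default_rng(5)
        levels = np.array([0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.75, 1.0])
        for _ in range(5):
            k = rng.integers(1, 29, size=len(levels)).astype(float)
            n = np.full(len(levels), 30.0)
            beta, ok = an._irls_logit(levels, k, n)
            assert ok
            import statsmodels.api as sm
            res = sm.GLM(np.column_stack([k, n - k]), sm.add_constant(levels),
                         family=sm.families.Binomial()).fit()
            assert np.allclose(beta, res.params, atol=1e-8)

    def test_all_identical_outcomes_flagged_degenerate(self):
        df = generate_logistic_outcomes(50, 0, n_per_level=5, seed=1)  # all avoid
        res = an.fit_avoidance_logistic(df)
        assert res.degenerate
        assert np.allclose(res.curve, 1.0)

    def test_complete_separation_flagged_with_empirical_step(self):
        levels = np.repeat([0.1, 0.4], 10)
        y = np.repeat([0, 1], 10)
        df = pd.DataFrame({
            "poison_level": levels, "final_poison_abundance": np.where(y, 950, 400),
            "under_pressure": y == 0, "predator_count_final": 100,
        })
        res = an.fit_avoidance_logistic(df)
        assert res.degenerate
        assert res.predict([0.1])[0] == 0.0
        assert res.predict([0.4])[0] == 1.0

    def test_single_level_is_an_input_error(self):
        df = generate_logistic_outcomes(0, 0, poison_levels=[0.1], n_per_level=10, seed=2)
        with pytest.raises(ValueError, match="2 distinct"):
            an.fit_avoidance_logistic(df)

    def test_summary_mentions_coefficients(self):
        df = generate_logistic_outcomes(-5, 22, n_per_level=30, seed=3)
        text = an.fit_avoidance_logistic(df).summary()
        assert "slope" in text and "intercept" in text


class TestBootstrapBand:
    def test_deterministic_given_seed(self):
        df = generate_logistic_outcomes(-5, 22, n_per_level=20, seed=4)
        a = an.bootstrap_curve_ci(df, n_boot=200, seed=11)
        b = an.bootstrap_curve_ci(df, n_boot=200, seed=11)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)

    def test_band_contains_point_curve(self):
        df = generate_logistic_outcomes(-4, 15, n_per_level=15, seed=6)
        res = an.fit_avoidance_logistic(df)
        band = res.bootstrap_band(n_boot=300, seed=7)
        assert np.all(band.lower <= res.curve + 1e-12)
        assert np.all(band.upper >= res.curve - 1e-12)

    def test_noiseless_pure_levels_give_zero_width_band(self):
        # per-level outcomes all-0 or all-1 resample to themselves, so every
        # refit is identical (interleaved pattern keeps the MLE finite)
        levels = np.repeat([0.1, 0.2, 0.3, 0.4], 8)
        y = np.tile(np.repeat([0, 1, 0, 1], 8), 1)
        df = pd.DataFrame({
            "poison_level": levels, "final_poison_abundance": np.where(y, 950, 400),
            "under_pressure": y == 0, "predator_count_final": 100,
        })
        band = an.bootstrap_curve_ci(df, n_boot=150, seed=8)
        assert np.allclose(band.lower, band.upper)

    def test_n_boot_floor(self):
        df = generate_logistic_outcomes(-5, 22, n_per_level=5, seed=9)
        with pytest.raises(ValueError):
            an.bootstrap_curve_ci(df, n_boot=50)


class TestTrajectorySummary:
    def test_identical_replicates_zero_width(self):
        recs = generate_timeseries_fixture({"poisonous": 800.0, "mimic": 500.0},
                                           noise_sd=0.0, n_replicates=4,
                                           n_updates=30, seed=10)
        ts = an.trajectory_summary(recs, n_boot=200, seed=1)
        assert np.allclose(ts["lower"], ts["mean"])
        assert np.allclose(ts["upper"], ts["mean"])

    def test_mean_curve_matches_known_means_exactly(self):
        ramp = lambda u: np.minimum(1000.0, 10.0 * u)
        recs = generate_timeseries_fixture(
            {"poisonous": ramp, "non-poisonous": 250.0, "predator": 40.0},
            noise_sd=0.0, n_replicates=3, n_updates=50, seed=11)
        ts = an.trajectory_summary(recs, n_boot=150, seed=2)
        pois = ts[ts["series"] == "poisonous"].set_index("update")["mean"]
        assert np.array_equal(pois.to_numpy(), ramp(pois.index.to_numpy()))
        assert (ts[ts["series"] == "predator"]["mean"] == 40.0).all()

    def test_band_contains_mean_under_noise(self):
        recs = generate_timeseries_fixture({"poisonous": 600.0}, noise_sd=40.0,
                                           n_replicates=8, n_updates=40, seed=12)
        ts = an.trajectory_summary(recs, n_boot=300, seed=3)
        assert np.all(ts["lower"] <= ts["mean"] + 1e-9)
        assert np.all(ts["upper"] >= ts["mean"] - 1e-9)

    def test_mismatched_grids_rejected(self):
        a = generate_timeseries_fixture({"poisonous": 10.0}, n_updates=10, seed=1)
        b = generate_timeseries_fixture({"poisonous": 10.0}, n_updates=20, seed=1)
        with pytest.raises(ValueError, match="recording grid"):
            an.trajectory_summary([a[0], b[0]], n_boot=100)


class TestDisplayProportions:
    def test_known_proportions_recovered_exactly(self):
        recs = generate_timeseries_fixture(
            {"mimic": 100.0}, noise_sd=0.0, n_replicates=1, n_updates=10,
            display_proportions=(0.10, 0.05, 0.85), seed=13)
        props = an.mimic_display_proportions(recs[0])
        assert np.allclose(props["displays_non_poisonous"], 0.10)
        assert np.allclose(props["displays_mimic"], 0.05)
        assert np.allclose(props["displays_poisonous"], 0.85)

    def test_rows_sum_to_one_where_defined(self):
        recs = generate_timeseries_fixture(
            {"mimic": 37.0}, noise_sd=0.0, n_replicates=1, n_updates=5,
            display_proportions=(0.3, 0.3, 0.4), seed=14)
        props = an.mimic_display_proportions(recs[0])
        total = (props["displays_non_poisonous"] + props["displays_mimic"]
                 + props["displays_poisonous"])
        assert np.allclose(total, 1.0)

    def test_no_mimics_reported_missing_not_zero(self):
        recs = generate_timeseries_fixture({"poisonous": 50.0, "mimic": 0.0},
                                           n_replicates=1, n_updates=5, seed=15)
        props = an.mimic_display_proportions(recs[0])
        assert props["displays_poisonous"].isna().all()


class TestMimicryRatio:
    def _records(self, prop, n=6, seed=0):
        return generate_timeseries_fixture(
            {"mimic": 100.0}, noise_sd=0.0, n_replicates=n, n_updates=10,
            display_proportions=(1.0 - prop, 0.0, prop), seed=seed)

    def test_identical_groups_ratio_one(self):
        recs = self._records(0.4)
        est = an.imperfect_mimicry_ratio(recs, recs, n_boot=200, seed=1)
        assert est.ratio == pytest.approx(1.0)

    def test_known_means_give_half(self):
        low = self._records(0.2, seed=2)
        perfect = self._records(0.4, seed=3)
        est = an.imperfect_mimicry_ratio(low, perfect, n_boot=200, seed=4)
        assert est.ratio == pytest.approx(0.5)

    def test_ci_reproducible_and_contains_point(self):
        rng_noise = generate_timeseries_fixture(
            {"mimic": 100.0}, noise_sd=6.0, n_replicates=8, n_updates=10,
            display_proportions=(0.5, 0.0, 0.5), seed=5)
        perfect = self._records(0.6, seed=6)
        a = an.imperfect_mimicry_ratio(rng_noise, perfect, n_boot=300, seed=7)
        b = an.imperfect_mimicry_ratio(rng_noise, perfect, n_boot=300, seed=7)
        assert a.ratio == b.ratio and a.ci95 == b.ci95
        assert a.ci95[0] <= a.ratio <= a.ci95[1]

    def test_zero_perfect_mean_flagged_undefined(self):
        low = self._records(0.3, seed=8)
        perfect = self._records(0.0, seed=9)
        est = an.imperfect_mimicry_ratio(low, perfect, n_boot=200, seed=10)
        assert est.undefined and np.isnan(est.ratio)
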