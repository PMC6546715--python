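"""Age-maturity engine: forest fits, selection, permutation, spline, scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from preterm_maturity import maturity
from preterm_maturity.errors import ConfigurationError, DataError


def _frame(arr, prefix="f"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"S{i:03d}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


@pytest.fixture(scope="module")
def informative_data():
    rng = np.random.default_rng(0)
    n = 100
    ages = rng.uniform(26, 40, size=n)
    # feature f0 equals age exactly; the rest are noise
    X = _frame(np.column_stack([ages] + [rng.normal(size=n) for _ in range(4)]))
    return X, ages


class TestFitAgeModel:
    def test_single_informative_feature_high_oob_spearman(self, informative_data):
        X, ages = informative_data
        fit = maturity.fit_age_model(X[["f0"]], ages, n_trees=200, seed=1)
        oob = fit.oob_predictions.dropna()
        rho, _ = spearmanr(oob, pd.Series(ages, index=X.index).loc[oob.index])
        assert rho > 0.95
        full = maturity.fit_age_model(X, ages, n_trees=200, seed=1)
        assert full.importance.index[0] == "f0"

    def test_constant_ages_warns_nonpositive_r2(self, informative_data):
        X, _ = informative_data
        with pytest.warns(UserWarning, match="constant"):
            fit = maturity.fit_age_model(X, np.full(len(X), 30.0), n_trees=20, seed=0)
        assert fit.oob_r2 <= 0

    def test_row_order_invariance(self, informative_data):
        X, ages = informative_data
        ages = pd.Series(ages, index=X.index)
        fit1 = maturity.fit_age_model(X, ages, n_trees=50, seed=2)
        perm = np.random.default_rng(5).permutation(len(X))
        fit2 = maturity.fit_age_model(X.iloc[perm], ages.iloc[perm], n_trees=50, seed=2)
        pd.testing.assert_series_equal(fit1.importance, fit2.importance)
        assert fit1.oob_mse == fit2.oob_mse

    def test_missing_values_rejected(self):
        X = _frame(np.ones((12, 2)))
        X.iloc[0, 0] = np.nan
        with pytest.raises(DataError, match="preprocessing"):
            maturity.fit_age_model(X, np.arange(12.0))


class TestFeatureGrid:
    def test_grid_contains_endpoints_and_decreases(self):
        for p in (1, 2, 7, 50, 100):
            grid = maturity._feature_grid(p)
            assert grid[0] == p and grid[-1] == 1
            assert all(a > b for a, b in zip(grid, grid[1:]))


class TestSelectSparseFeatures:
    def _cv(self, grid, mse):
        return maturity.CvCurve(list(grid), list(mse), grid[0])

    def test_flat_curve_selects_smallest(self):
        imp = pd.Series(np.arange(10, 0, -1), index=[f"f{i}" for i in range(10)])
        cv = self._cv([10, 8, 6, 4, 2, 1], [1.0] * 6)
        assert maturity.select_sparse_features(cv, imp) == ["f0"]

    def test_error_rises_below_eight_features(self):
        """Flat CV error down to 8 features, rising steeply below: the sparse
        model keeps the top 8 (the reduced-model pattern)."""
        grid = [20, 15, 11, 8, 6, 4, 2, 1]
        mse = [1.0, 1.01, 1.0, 1.02, 1.5, 2.0, 3.0, 5.0]
        imp = pd.Series(np.arange(20, 0, -1), index=[f"f{i:02d}" for i in range(20)])
        selected = maturity.select_sparse_features(self._cv(grid, mse), imp)
        assert len(selected) == 8
        assert selected == [f"f{i:02d}" for i in range(8)]

    def test_zero_tolerance_takes_argmin(self):
        grid = [10, 5, 1]
        mse = [1.2, 1.0, 1.1]
        imp = pd.Series(np.arange(10, 0, -1), index=[f"f{i}" for i in range(10)])
        assert len(maturity.select_sparse_features(self._cv(grid, mse), imp, tol=0.0)) == 5


class TestCrossValidation:
    def test_planted_signal_recovered_sparsely(self):
        """5 informative + 45 noise features: cross-validated selection keeps
        a small set containing most informative features."""
        rng = np.random.default_rng(4)
        n = 150
        ages = rng.uniform(26, 40, size=n)
        info = np.column_stack(
            [ages * w + rng.normal(0, 2.0, n) for w in (1.0, -0.8, 0.6, 0.5, -0.4)]
        )
        noise = rng.normal(size=(n, 45))
        X = _frame(np.column_stack([info, noise]))
        infants = [f"I{i % 30}" for i in range(n)]
        cv = maturity.cross_validate_feature_counts(
            X, ages, infants, folds=4, n_trees=60, seed=0
        )
        assert cv.n_features_grid[0] == 50 and cv.n_features_grid[-1] == 1
        full = maturity.fit_age_model(X, ages, n_trees=200, seed=0)
        selected = maturity.select_sparse_features(cv, full.importance)
        informative = {"f0", "f1", "f2", "f3", "f4"}
        assert len(selected) <= 20
        assert len(informative & set(selected)) >= 4

    def test_excess_folds_degrade_to_loio(self, informative_data):
        X, ages = informative_data
        infants = [f"I{i % 5}" for i in range(len(X))]
        with pytest.warns(UserWarning, match="leave-one-infant-out"):
            cv = maturity.cross_validate_feature_counts(
                X, ages, infants, folds=50, n_trees=10, seed=0
            )
        assert cv.selected_n in cv.n_features_grid


class TestPermutationTest:
    def test_p_value_formula_trivial_cases(self):
        res = maturity.PermutationResult(1.0, [2.0, 3.0], (1 + 0) / 3)
        assert res.p_value == pytest.approx(1 / 3)
        # direct: strong signal beats all nulls
        rng = np.random.default_rng(1)
        ages = rng.uniform(26, 40, 40)
        X = _frame(ages[:, None] + rng.normal(0, 0.1, (40, 1)))
        res = maturity.permutation_test(X, ages, ["f0"], n_perm=19, n_trees=30, seed=0)
        assert res.p_value == pytest.approx(1 / 20)
        assert min(res.null_stats) > res.observed_stat

    def test_single_permutation_null_not_better(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(20, 2)))
        ages = rng.uniform(26, 40, 20)
        res = maturity.permutation_test(X, ages, ["f0"], n_perm=1, n_trees=10, seed=3)
        assert res.p_value in (0.5, 1.0)

    def test_invalid_n_perm(self):
        X = _frame(np.ones((12, 1)))
        with pytest.raises(ConfigurationError, match="n_perm"):
            maturity.permutation_test(X, np.arange(12.0), ["f0"], n_perm=0)


class TestReferenceSpline:
    def test_reproduces_line(self):
        pma = np.linspace(26, 40, 30)
        pred = 2.0 + 0.9 * pma
        spline = maturity.fit_reference_spline(pred, pma)
        np.testing.assert_allclose(spline(pma), pred, atol=1e-6)

    def test_residuals_centered(self):
        rng = np.random.default_rng(6)
        pma = rng.uniform(26, 40, 200)
        pred = 0.8 * pma + rng.normal(0, 1.5, 200)
        spline = maturity.fit_reference_spline(pred, pma)
        assert abs(spline.residuals.mean()) < 0.01 * pred.std()

    def test_clamps_outside_domain(self):
        pma = np.array([30.0, 32.0, 34.0, 36.0, 38.0])
        pred = np.array([29.0, 31.0, 35.0, 36.0, 39.0])
        spline = maturity.fit_reference_spline(pred, pma)
        assert spline(20.0) == pytest.approx(spline(30.0))
        assert spline(50.0) == pytest.approx(spline(38.0))

    def test_too_few_distinct_pma_errors(self):
        with pytest.raises(DataError, match="distinct PMA"):
            maturity.fit_reference_spline([1, 2, 3], [30, 30, 31])


class TestForAgeZ:
    def _ref(self, ages, pma=31.0):
        return pd.DataFrame(
            {"pma_weeks": [pma] * len(ages), "predicted_age": ages},
            index=[f"R{i}" for i in range(len(ages))],
        )

    def _scores(self, age, pma=31.0):
        return pd.DataFrame(
            {"pma_weeks": [pma], "predicted_age": [age]}, index=["S0"]
        )

    def test_median_reference_scores_zero(self):
        z = maturity.for_age_z(self._scores(32.0), self._ref([30.0, 32.0, 34.0]))
        assert z["S0"] == 0.0

    def test_hand_computed_z(self):
        z = maturity.for_age_z(self._scores(34.0), self._ref([30.0, 32.0, 34.0]))
        assert z["S0"] == pytest.approx(1.0)  # (34-32)/sample SD 2

    def test_reference_self_median_exactly_zero_per_bin(self):
        rng = np.random.default_rng(7)
        ref = pd.DataFrame(
            {
                "pma_weeks": rng.uniform(26, 42, 81),
                "predicted_age": rng.uniform(26, 42, 81),
            },
            index=[f"R{i}" for i in range(81)],
        )
        z = maturity.for_age_z(ref, ref)
        bins = maturity._bin_index(ref["pma_weeks"].to_numpy(), maturity.DEFAULT_BINS)
        for b in np.unique(bins):
            med = np.median(z[bins == b])
            if (bins == b).sum() % 2 == 1:
                # the middle sample's own z is (x - x)/sd = 0 exactly
                assert med == 0.0
            else:
                # mean of two exactly-opposite values, up to rounding
                assert abs(med) < 1e-12

    def test_sparse_bin_errors(self):
        with pytest.raises(DataError, match="bin"):
            maturity.for_age_z(self._scores(30.0, pma=39.0), self._ref([30.0, 31.0]))

    def test_bins_are_half_open(self):
        ref = pd.concat(
            [self._ref([28.0, 30.0], pma=29.0), self._ref([31.0, 33.0], pma=30.0)]
        )
        ref.index = ["R0", "R1", "R2", "R3"]
        z_left = maturity.for_age_z(self._scores(32.0, pma=30.0), ref)
        # PMA exactly 30 falls in the [30, 34) bin: median 32, sd sqrt(2)
        assert z_left["S0"] == pytest.approx(0.0)


class TestEndToEndScoring:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(8)
        n = 150
        pma = rng.uniform(26, 40, n)
        X = _frame(
            np.column_stack(
                [pma + rng.normal(0, 1.0, n), 40 - pma + rng.normal(0, 1.0, n),
                 rng.normal(size=(n, 3)).T.reshape(n, 3)]
            )
        )
        infants = [f"I{i % 40}" for i in range(n)]
        model = maturity.train_maturity_model(
            X, pma, infants, n_trees=100, n_features=2, n_perm=0, seed=0
        )
        return model, X, pma

    def test_reference_cohort_relative_maturity_near_zero(self, trained):
        model, X, pma = trained
        scores = maturity.score_maturity(model, X, pma)
        assert abs(scores["relative_maturity"].mean()) < 0.5

    def test_sample_on_spline_has_zero_relative_maturity(self, trained):
        model, X, pma = trained
        scores = maturity.score_maturity(model, X, pma)
        manual = scores["predicted_age"] - model.spline(scores["pma_weeks"])
        np.testing.assert_allclose(scores["relative_maturity"], manual)

    def test_feature_mismatch_lists_missing(self, trained):
        model, X, pma = trained
        with pytest.raises(DataError, match=model.feature_ids[0]):
            maturity.score_maturity(model, X.drop(columns=model.feature_ids[:1]), pma)

    def test_save_load_round_trip(self, trained, tmp_path):
        model, X, pma = trained
        path = tmp_path / "model.joblib"
        maturity.save_model(model, path)
        back = maturity.load_model(path)
        probe = X[model.feature_ids].to_numpy()
        np.testing.assert_array_equal(
            model.forest.predict(probe), back.forest.predict(probe)
        )
        assert back.feature_ids == model.feature_ids
        assert back.n_trees == model.n_trees
        assert back.seed == model.seed

    def test_corrupted_archive_errors(self, tmp_path):
        path = tmp_path / "bad.joblib"
        path.write_bytes(b"not a model")
        with pytest.raises(DataError):
            maturity.load_model(path)


class TestDelayRecovery:
    def test_growth_failure_scores_negative_and_monotone_in_delay(self):
        """Median relative maturity of the delayed group is negative and its
        magnitude grows with the planted delay."""
        from preterm_maturity import microbiome, simulate

        medians = {}
        for delay in (0.0, 1.5, 3.0):
            cfg = simulate.SimulationConfig(
                n_infants=24, prop_growth_failure=0.5, n_taxa=40, n_age_taxa=10,
                delay_weeks=delay, seed=30,
                library_size_log_mean=np.log(8000.0), library_size_log_sd=0.2,
            )
            meta, _ = simulate.generate_metadata(cfg)
            counts = simulate.generate_counts(meta, cfg)
            rarefied, _ = microbiome.rarefy(counts, depth=4000, seed=0)
            meta = meta.loc[rarefied.sample_ids]
            X = rarefied.counts.T.astype(float)
            ag = meta.index[meta["group"] == "appropriate"]
            model = maturity.train_maturity_model(
                X.loc[ag], meta.loc[ag, "pma_weeks"], meta.loc[ag, "infant_id"],
                n_trees=100, n_features=10, n_perm=0, seed=0,
            )
            gf = meta.index[meta["group"] == "growth_failure"]
            scores = maturity.score_maturity(
                model, X.loc[gf], meta.loc[gf, "pma_weeks"], reference=False
            )
            medians[delay] = scores["relative_maturity"].median()
        assert medians[1.5] < 0 and medians[3.0] < 0
        assert medians[3.0] < medians[1.5] < medians[0.0] + 0.5
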