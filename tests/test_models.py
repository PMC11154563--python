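import numpy as np
import pandas as pd
import pytest

from ppghb.core_io import filter_complete, load_clinical_fixture
from ppghb.models import (
    Dataset,
    GridSpec,
    bland_altman,
    fit_predict,
    grid_search_cv,
    pearson_matrix,
    regression_metrics,
    split_7_3,
)


def linear_dataset(n=60, seed=0, noise=2.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 3))
    y = 100.0 + 40.0 * X[:, 0] - 20.0 * X[:, 1] + noise * rng.normal(size=n)
    return Dataset(X, y)


class TestSplit:
    def test_56_rows_split_39_17(self):
        ds = linear_dataset(56)
        train, test = split_7_3(ds, seed=1)
        assert (train.n, test.n) == (39, 17)

    def test_10_rows_split_7_3(self):
        train, test = split_7_3(linear_dataset(10), seed=0)
        assert (train.n, test.n) == (7, 3)

    def test_deterministic_and_exhaustive(self):
        ds = linear_dataset(30)
        t1 = split_7_3(ds, seed=5)
        t2 = split_7_3(ds, seed=5)
        np.testing.assert_array_equal(t1[0].y, t2[0].y)
        all_y = np.sort(np.concatenate([t1[0].y, t1[1].y]))
        np.testing.assert_array_equal(all_y, np.sort(ds.y))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            split_7_3(linear_dataset(8), seed=0)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        ds = linear_dataset(30)
        grid = GridSpec("adaboost", n_estimators=(3,), max_depth=(2,))
        res = grid_search_cv(ds, grid, k=5, seed=0)
        assert res.best_params == {"n_estimators": 3, "max_depth": 2}
        assert len(res.best.fold_metrics) == 5

    def test_linear_data_recovered_by_adaboost_grid(self):
        ds = linear_dataset(60, noise=1.0)
        res = grid_search_cv(ds, GridSpec("adaboost"), k=10, seed=0)
        assert res.best.mean_r2 > 0.8

    def test_leave_one_out_boundary(self):
        ds = linear_dataset(12)
        grid = GridSpec("adaboost", n_estimators=(2,), max_depth=(1,))
        with pytest.warns(UserWarning):  # single-row folds: R² undefined
            res = grid_search_cv(ds, grid, k=12, seed=0)
        assert len(res.best.fold_metrics) == 12

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            grid_search_cv(linear_dataset(5), GridSpec("adaboost"), k=10)


class TestFitPredict:
    def test_constant_targets_predicted_exactly(self):
        ds = Dataset(np.arange(20.0).reshape(-1, 1), np.full(20, 123.0))
        test = Dataset(np.array([[3.0], [15.0]]), np.array([123.0, 123.0]))
        pred = fit_predict("adaboost", {"n_estimators": 3, "max_depth": 2},
                           ds, test, seed=0)
        np.testing.assert_allclose(pred, 123.0)

    def test_stump_forest_is_piecewise_constant(self):
        ds = linear_dataset(40)
        pred = fit_predict("random_forest", {"n_estimators": 1, "max_depth": 1},
                           ds, ds, seed=0)
        assert np.unique(pred).size <= 2

    def test_bpnn_identity_lbfgs_fits_linear_data(self):
        ds = linear_dataset(60, noise=0.5)
        train, test = split_7_3(ds, seed=0)
        params = {"activation": "identity", "solver": "lbfgs",
                  "hidden_layer_sizes": (16, 8), "max_iter": 10_000}
        pred = fit_predict("bpnn", params, train, test, seed=0)
        r2, _, _ = regression_metrics(test.y, pred)
        assert r2 > 0.95


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        assert regression_metrics([1.0, 2.0], [1.0, 2.0]) == (1.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        r2, mse, mae = regression_metrics([100.0, 120.0], [110.0, 110.0])
        assert (mse, mae) == (100.0, 10.0)
        assert r2 == 0.0

    def test_mean_predictor_scores_zero(self, rng):
        y = rng.normal(size=50)
        r2, _, _ = regression_metrics(y, np.full(50, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_targets_warn(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r2, mse, mae = regression_metrics([5.0, 5.0], [4.0, 6.0])
        assert r2 is None
        assert mse == 1.0

    def test_agrees_with_direct_formulas_on_random_vectors(self, rng):
        y = rng.normal(100, 15, size=200)
        p = y + rng.normal(0, 5, size=200)
        r2, mse, mae = regression_metrics(y, p)
        assert mse == pytest.approx(np.mean((y - p) ** 2), rel=1e-12)
        assert mae == pytest.approx(np.mean(np.abs(y - p)), rel=1e-12)
        assert r2 == pytest.approx(
            1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), rel=1e-12)


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (ba.mean_diff, ba.lower_limit, ba.upper_limit, ba.outside_count) \
            == (0.0, 0.0, 0.0, 0)

    def test_symmetric_differences(self):
        # d = (+2, -2): mean 0, population SD 2, limits ±3.92
        ba = bland_altman([0.0, 0.0], [2.0, -2.0])
        assert ba.mean_diff == 0.0
        assert ba.upper_limit == pytest.approx(3.92)
        assert ba.lower_limit == pytest.approx(-3.92)

    def test_gaussian_coverage(self, rng):
        y = np.zeros(100)
        pred = rng.standard_normal(100)
        ba = bland_altman(y, pred)
        assert abs(ba.outside_count - 5) <= 4

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestPearsonMatrix:
    def test_unit_diagonal_and_exact_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0],
                           "z": [6.0, 4.0, 2.0]})
        corr = pearson_matrix(df)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        assert corr.loc["x", "z"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_zero_variance_column_is_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        corr = pearson_matrix(df)
        assert np.isnan(corr.loc["x", "c"])

    def test_fixture_hemoglobin_creatinine_matches_direct_formula(self):
        complete = filter_complete(load_clinical_fixture(),
                                   ("blood_pressure", "creatinine", "urea"))
        df = complete.to_frame()
        corr = pearson_matrix(df)
        hb = df["hemoglobin_g_per_L"].to_numpy()
        cr = df["creatinine_umol_per_L"].to_numpy()
        expected = np.corrcoef(hb, cr)[0, 1]
        assert corr.loc["hemoglobin_g_per_L", "creatinine_umol_per_L"] == \
            pytest.approx(expected, rel=1e-12)

    def test_pairwise_complete_on_fixture(self):
        corr = pearson_matrix(load_clinical_fixture().to_frame())
        # hemoglobin and creatinine share only the 16 complete rows, but the
        # pairwise-complete coefficient must still be defined
        assert np.isfinite(corr.loc["hemoglobin_g_per_L", "creatinine_umol_per_L"])
        assert corr.abs().max().max() <= 1.0 + 1e-12
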