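import numpy as np
import pytest
from scipy import stats

from chromaroi.errors import DegenerateInputError, DomainError, ShapeError
from chromaroi.pls import (
    bias_t_test,
    figures_of_merit,
    fit_pls,
    loocv,
    loocv_curve,
    pick_lv,
    predict,
    select_lv,
)


def _random_problem(seed, I=12, J=7, informative=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(I, J))
    beta = np.zeros(J)
    beta[:informative] = rng.normal(size=informative)
    y = X @ beta + 0.05 * rng.normal(size=I)
    return X, y


class TestFit:
    def test_single_informative_column_one_lv(self):
        rng = np.random.default_rng(1)
        X = np.zeros((10, 4))
        X[:, 2] = rng.normal(size=10)
        y = 3.0 * X[:, 2] + 1.0
        model = fit_pls(X, y, 1)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_lv_equals_least_squares(self, seed):
        """At the full component count PLS reproduces the OLS fit."""
        rng = np.random.default_rng(seed)
        I, J = 10, 6
        X = rng.normal(size=(I, J))
        y = rng.normal(size=I)
        model = fit_pls(X, y, J)
        Xc = X - X.mean(axis=0)
        b = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), y.mean() + Xc @ b, atol=1e-8)

    def test_column_mean_input_predicts_mean_response(self):
        X, y = _random_problem(3)
        model = fit_pls(X, y, 3)
        assert predict(model, X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_matches_sklearn_nipals(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(4)
        model = fit_pls(X, y, 3)
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            predict(model, X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_n_lv_out_of_range(self):
        X, y = _random_problem(0, I=5, J=3)
        with pytest.raises(DomainError):
            fit_pls(X, y, 5)

    def test_zero_variance_response(self):
        X, _ = _random_problem(0)
        with pytest.raises(DegenerateInputError):
            fit_pls(X, np.ones(X.shape[0]), 2)


class TestPredict:
    def test_training_rows_give_fitted_values(self):
        X, y = _random_problem(5)
        model = fit_pls(X, y, 2)
        a = predict(model, X)
        b = np.array([predict(model, X[i][None, :])[0] for i in range(len(y))])
        np.testing.assert_allclose(a, b)

    def test_duplicated_row_duplicated_prediction(self):
        X, y = _random_problem(6)
        model = fit_pls(X, y, 2)
        two = predict(model, np.vstack([X[0], X[0]]))
        assert two[0] == two[1]

    def test_regression_vector_oracle(self):
        """Prediction equals explicit multiplication by the b-vector."""
        X, y = _random_problem(7)
        model = fit_pls(X, y, 3)
        manual = model.y_mean + (X - model.x_mean) @ model.coef
        np.testing.assert_allclose(predict(model, X), manual)

    def test_shape_mismatch(self):
        X, y = _random_problem(0)
        model = fit_pls(X, y, 2)
        with pytest.raises(ShapeError):
            predict(model, X[:, :3])

    def test_zero_weight_column_shift_invariance(self):
        # a constant column gets zero weight; shifting it cannot move
        # predictions (centring sanity)
        X, y = _random_problem(8)
        X = np.column_stack([X, np.full(X.shape[0], 5.0)])
        model = fit_pls(X, y, 3)
        X_shift = X.copy()
        X_shift[:, -1] += 17.0
        np.testing.assert_allclose(predict(model, X_shift), predict(model, X))


class TestLOOCV:
    def test_equals_naive_refit_loop_bitwise(self):
        X, y = _random_problem(9)
        for n_lv in (1, 2, 4):
            rmsecv, preds = loocv(X, y, n_lv)
            naive = np.empty(len(y))
            for i in range(len(y)):
                keep = np.arange(len(y)) != i
                m = fit_pls(X[keep], y[keep], n_lv)
                naive[i] = predict(m, X[i][None, :])[0]
            assert np.array_equal(preds, naive)
            assert rmsecv == np.sqrt(np.mean((naive - y) ** 2))

    def test_matches_independent_sklearn_loop(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(10)
        rmsecv, preds = loocv(X, y, 2)
        naive = np.empty(len(y))
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            sk = sklearn.PLSRegression(n_components=2, scale=False).fit(
                X[keep], y[keep]
            )
            naive[i] = sk.predict(X[i][None, :]).ravel()[0]
        np.testing.assert_allclose(preds, naive, atol=1e-8)

    def test_curve_consistent_with_fixed_lv(self):
        X, y = _random_problem(11)
        curve, _ = loocv_curve(X, y, 4)
        for n_lv in (1, 2, 3, 4):
            assert loocv(X, y, n_lv)[0] == pytest.approx(curve[n_lv - 1])

    def test_too_many_components(self):
        X, y = _random_problem(0, I=6)
        with pytest.raises(DomainError):
            loocv(X, y, 5)

    def test_constant_response_rejected(self):
        X, _ = _random_problem(0)
        with pytest.raises(DegenerateInputError):
            loocv(X, np.full(X.shape[0], 2.0), 1)


class TestLVSelection:
    def test_strictly_decreasing_curve(self):
        assert pick_lv([3.0, 2.0, 1.0]) == 3

    def test_flat_curve_breaks_to_one(self):
        assert pick_lv([2.0, 2.0, 2.0]) == 1

    def test_tolerance_prefers_fewer_components(self):
        # minimum at LV4, but LV2 lies within 5% of it
        assert pick_lv([3.0, 2.52, 2.6, 2.4], tol=0.05) == 2
        assert pick_lv([3.0, 2.52, 2.6, 2.4], tol=0.0) == 4

    def test_select_lv_finds_true_dimension(self):
        rng = np.random.default_rng(2)
        T = rng.normal(size=(30, 2))
        P = rng.normal(size=(2, 8))
        X = T @ P + 0.01 * rng.normal(size=(30, 8))
        y = T @ np.array([1.0, -2.0]) + 0.01 * rng.normal(size=30)
        assert select_lv(X, y, 5, tol=0.02) == 2


class TestMerits:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = figures_of_merit(y, y)
        assert m["rmse"] == 0.0 and m["r2"] == 1.0

    def test_alternating_errors(self):
        y = np.array([10.0, 10.0, 10.0, 10.0])
        m = figures_of_merit(y, y + np.array([3.0, -3.0, 3.0, -3.0]))
        assert m["rmse"] == pytest.approx(3.0)

    def test_rep_ratio(self):
        # RMSE 2.8 on responses averaging 20 -> REP 0.14
        rng = np.random.default_rng(0)
        y = np.array([15.0, 25.0, 18.0, 22.0])
        e = np.array([2.8, -2.8, 2.8, -2.8])
        m = figures_of_merit(y, y + e)
        assert m["rep"] == pytest.approx(2.8 / 20.0)

    def test_zero_mean_response_rejected(self):
        with pytest.raises(DegenerateInputError):
            figures_of_merit(np.array([-1.0, 1.0]), np.array([0.0, 0.0]))


class TestBiasTest:
    def test_critical_value_df9(self):
        y = np.arange(10, dtype=float) + 1
        out = bias_t_test(y, y + np.linspace(-1, 1, 10))
        assert out["t_crit"] == pytest.approx(1.8331, abs=5e-5)

    def test_symmetric_residuals_not_significant(self):
        y = np.zeros(6)
        e = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        out = bias_t_test(y, y + e)
        assert out["bias"] == 0.0 and out["t_cal"] == 0.0
        assert not out["significant"]

    def test_matches_one_sample_t_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        e = rng.normal(loc=0.4, size=12)
        out = bias_t_test(y, y + e)
        t_stat = stats.ttest_1samp(e, 0.0).statistic
        assert out["t_cal"] == pytest.approx(abs(t_stat))
        assert out["significant"] == (
            abs(t_stat) > stats.t.ppf(0.95, len(e) - 1)
        )

    def test_zero_spread_residuals(self):
        y = np.zeros(5)
        with pytest.raises(DegenerateInputError):
            bias_t_test(y, y + 1.0)
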