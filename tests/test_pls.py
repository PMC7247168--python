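import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsel.pls import (
    PredictionRecord,
    fit_pls,
    loocv_predict,
    loocv_predict_multi,
    predict,
    r_pcv,
    secv,
    select_factors,
)


def ols_predictions(X, y, X_new=None):
    """Least-squares oracle with intercept, via lstsq on the augmented matrix."""
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    Xn = X if X_new is None else X_new
    return np.hstack([np.ones((Xn.shape[0], 1)), Xn]) @ beta


class TestFitPredict:
    def test_noiseless_rank2(self, rng):
        T = rng.normal(size=(20, 2))
        P = rng.normal(size=(2, 6))
        X = T @ P
        y = T @ np.array([1.5, -2.0])
        m = fit_pls(X, y, 2)
        assert np.abs(predict(m, X) - y).max() < 1e-8

    def test_max_factors_equals_ols(self, rng):
        for _ in range(10):
            X = rng.normal(size=(15, 5))
            y = rng.normal(size=15)
            m = fit_pls(X, y, 5)
            np.testing.assert_allclose(predict(m, X), ols_predictions(X, y), atol=1e-6)

    def test_single_column_is_simple_regression(self, rng):
        x = rng.normal(size=12)
        y = 3.0 + 2.0 * x + rng.normal(0, 0.1, size=12)
        m = fit_pls(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        np.testing.assert_allclose(m.coef[0], slope, atol=1e-10)
        np.testing.assert_allclose(predict(m, x[:, None]), intercept + slope * x, atol=1e-10)

    def test_mean_maps_to_mean(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        m = fit_pls(X, y, 2)
        np.testing.assert_allclose(predict(m, m.x_mean[None, :])[0], m.y_mean, atol=1e-12)

    def test_duplicated_rows_duplicated_predictions(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        m = fit_pls(X, y, 2)
        two = predict(m, np.vstack([X[0], X[0]]))
        assert two[0] == two[1]

    def test_factor_bound_enforced(self, rng):
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        with pytest.raises(ValueError):
            fit_pls(X, y, 5)  # n-1 = 4

    def test_zero_variance_y(self, rng):
        with pytest.raises(ValueError):
            fit_pls(rng.normal(size=(6, 3)), np.ones(6), 1)

    def test_shape_mismatch_on_predict(self, rng):
        m = fit_pls(rng.normal(size=(8, 3)), rng.normal(size=8), 1)
        with pytest.raises(ValueError):
            predict(m, rng.normal(size=(2, 4)))


class TestLoocv:
    def test_noiseless_linear_gives_zero_secv(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        rec = loocv_predict(X, y, 3)
        assert secv(rec) < 1e-8

    def test_three_sample_hand_oracle(self):
        # three folds, each a 2-point simple regression (line through 2 points)
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 2.5])
        expected = []
        for i in range(3):
            keep = [j for j in range(3) if j != i]
            x0, x1 = x[keep]
            y0, y1 = y[keep]
            slope = (y1 - y0) / (x1 - x0)
            expected.append(y0 + slope * (x[i] - x0))
        rec = loocv_predict(x[:, None], y, 1)
        np.testing.assert_allclose(rec.predicted, expected, atol=1e-10)

    def test_order_invariance(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        perm = rng.permutation(10)
        a = loocv_predict(X, y, 2).predicted
        b = loocv_predict(X[perm], y[perm], 2).predicted
        np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_matches_leave_one_out_ols_at_max_factors(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        rec = loocv_predict(X, y, 4)
        for i in range(12):
            keep = np.arange(12) != i
            exp = ols_predictions(X[keep], y[keep], X[i : i + 1])[0]
            assert abs(rec.predicted[i] - exp) < 1e-6

    def test_infeasible_factor_count(self, rng):
        with pytest.raises(ValueError):
            loocv_predict_multi(rng.normal(size=(5, 10)), rng.normal(size=5), 4)


class TestMetrics:
    def test_secv_zero_iff_equal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert secv(PredictionRecord(v, v.copy())) == 0.0
        assert secv(PredictionRecord(v, v + 1e-9)) > 0.0

    def test_secv_hand_values(self):
        assert secv(PredictionRecord([0.0, 0.0], [1.0, -1.0])) == 1.0
        got = secv(PredictionRecord([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8]))
        np.testing.assert_allclose(got, np.sqrt(0.025), atol=1e-12)

    def test_r_pcv_affine(self):
        m = np.array([1.0, 2.0, 4.0, 8.0])
        assert r_pcv(PredictionRecord(m, 2 * m + 1)) == pytest.approx(1.0)
        assert r_pcv(PredictionRecord(m, -m)) == pytest.approx(-1.0)

    def test_r_pcv_degenerate(self):
        with pytest.raises(ValueError):
            r_pcv(PredictionRecord([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            PredictionRecord([1.0, 2.0], [1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(3, 40))
    def test_metric_ranges(self, seed, n):
        rng = np.random.default_rng(seed)
        rec = PredictionRecord(rng.normal(size=n), rng.normal(size=n))
        assert secv(rec) >= 0.0
        assert -1.0 <= r_pcv(rec) <= 1.0


class TestSelectFactors:
    def test_two_latent_factors_forced(self, rng):
        T = rng.normal(size=(25, 2))
        X = T @ rng.normal(size=(2, 8))
        y = T @ np.array([2.0, -1.0])
        f, rec = select_factors(X, y, range(1, 6))
        assert f == 2
        assert secv(rec) < 1e-6

    def test_single_entry_grid(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        f, _ = select_factors(X, y, [3])
        assert f == 3

    def test_grid_order_invariance(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        f1, _ = select_factors(X, y, [1, 2, 3, 4, 5])
        f2, _ = select_factors(X, y, [5, 3, 1, 4, 2])
        assert f1 == f2

    def test_infeasible_entries_skipped(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        f, _ = select_factors(X, y, range(1, 21))
        assert 1 <= f <= 3

    def test_all_infeasible(self, rng):
        with pytest.raises(ValueError):
            select_factors(rng.normal(size=(6, 3)), rng.normal(size=6), [10, 20])
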