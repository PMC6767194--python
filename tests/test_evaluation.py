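import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from algaftir.evaluation import (
    OutlierPolicy,
    PredictionPairs,
    apply_outlier_policy,
    kfold_cv,
    loo_cv,
    q_squared,
    r_squared,
    rmse_c_or_p,
    rmsecv,
    rpd,
)
from algaftir.ulra import fit_ulra, predict_ulra


def pairs(y_true, y_pred, context="calibration"):
    return PredictionPairs(list(range(len(y_true))), y_true, y_pred, context)


# ---- independent brute-force oracles (plain python loops) ----------------

def oracle_rmse(yt, yp, den):
    s = 0.0
    for a, b in zip(yt, yp):
        s += (b - a) ** 2
    return math.sqrt(s / den)


def oracle_r2(yt, yp, mean=None):
    m = sum(yt) / len(yt) if mean is None else mean
    ss_res = sum((b - a) ** 2 for a, b in zip(yt, yp))
    ss_tot = sum((a - m) ** 2 for a in yt)
    return 1 - ss_res / ss_tot


def oracle_sd(y):
    m = sum(y) / len(y)
    return math.sqrt(sum((v - m) ** 2 for v in y) / (len(y) - 1))


class TestStatisticOracles:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        p = pairs(y, y)
        assert rmse_c_or_p(p) == 0.0
        assert r_squared(p) == 1.0

    def test_two_point_conventions(self):
        p = pairs(np.array([0.0, 0.0]), np.array([1.0, -1.0]))
        assert rmse_c_or_p(p) == pytest.approx(1.0)
        assert rmsecv(p) == pytest.approx(math.sqrt(2.0))

    def test_rmsecv_identity_with_rmsec(self):
        rng = np.random.default_rng(7)
        yt = rng.normal(size=17)
        yp = yt + rng.normal(size=17)
        p = pairs(yt, yp)
        assert rmsecv(p) == pytest.approx(rmse_c_or_p(p) * math.sqrt(17 / 16))

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = pairs(y, np.full(4, y.mean()))
        assert r_squared(p) == pytest.approx(0.0)

    def test_rpd_definition(self):
        y = np.array([1.0, 3.0, 5.0, 7.0])
        assert rpd(y, oracle_sd(list(y)) / 2) == pytest.approx(2.0)

    def test_rpd_constant_y_rejected(self):
        with pytest.raises(ValueError):
            rpd(np.ones(5), 1.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_all_statistics_match_loop_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        yt = rng.normal(20, 8, n)
        yp = yt + rng.normal(0, 3, n)
        p = pairs(yt, yp)
        pcv = pairs(yt, yp, "cross_validation")
        assert rmse_c_or_p(p) == pytest.approx(oracle_rmse(yt, yp, n), rel=1e-10)
        assert rmsecv(pcv) == pytest.approx(oracle_rmse(yt, yp, n - 1), rel=1e-10)
        assert r_squared(p) == pytest.approx(oracle_r2(yt, yp), rel=1e-10)
        mean = float(yt.mean())
        assert q_squared(pcv, mean) == pytest.approx(oracle_r2(yt, yp, mean), rel=1e-10)
        rm = rmsecv(pcv)
        assert rpd(yt, rm) == pytest.approx(oracle_sd(list(yt)) / rm, rel=1e-10)


@st.composite
def residual_pairs(draw):
    n = draw(st.integers(3, 25))
    yt = draw(
        st.lists(st.floats(-100, 100), min_size=n, max_size=n).filter(
            lambda v: np.std(v) > 1e-6
        )
    )
    off = draw(st.lists(st.floats(-10, 10), min_size=n, max_size=n))
    return np.array(yt), np.array(yt) + np.array(off)


class TestStatisticProperties:
    @given(residual_pairs())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rmse_nonnegative_and_r2_bounded(self, yp_pair):
        yt, yp = yp_pair
        p = pairs(yt, yp)
        assert rmse_c_or_p(p) >= 0
        assert r_squared(p) <= 1.0

    @given(residual_pairs())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rmsecv_exceeds_rmsec_by_fixed_factor(self, yp_pair):
        yt, yp = yp_pair
        n = len(yt)
        p = pairs(yt, yp)
        assert rmsecv(p) == pytest.approx(
            rmse_c_or_p(p) * math.sqrt(n / (n - 1)), rel=1e-9
        )


def ulra_fit(x, y):
    m = fit_ulra(np.asarray(x).ravel(), y)
    return lambda xe: predict_ulra(m, np.asarray(xe).ravel())


class TestCrossValidation:
    def test_loo_exact_on_collinear_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(-1, 1)
        y = 2 * x.ravel() + 1
        cv = loo_cv(ulra_fit, x, y)
        np.testing.assert_allclose(cv.residuals, 0, atol=1e-10)

    def test_loo_equals_manual_holdouts(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = 3 * x + rng.normal(size=5)
        cv = loo_cv(ulra_fit, x.reshape(-1, 1), y)
        for i in range(5):
            mask = np.arange(5) != i
            m = fit_ulra(x[mask], y[mask])
            assert cv.y_pred[i] == pytest.approx(predict_ulra(m, x[i]), rel=1e-12)

    def test_loo_order_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=8)
        y = 2 * x + rng.normal(size=8)
        cv1 = loo_cv(ulra_fit, x.reshape(-1, 1), y)
        perm = rng.permutation(8)
        cv2 = loo_cv(ulra_fit, x[perm].reshape(-1, 1), y[perm])
        assert sorted(np.round(cv1.residuals, 12)) == sorted(np.round(cv2.residuals, 12))

    def test_kfold_k_equals_n_is_loo(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=9)
        y = 2 * x + rng.normal(size=9)
        loo = loo_cv(ulra_fit, x.reshape(-1, 1), y)
        kf = kfold_cv(ulra_fit, x.reshape(-1, 1), y, k=9, seed=0)
        np.testing.assert_allclose(kf.y_pred, loo.y_pred, rtol=1e-12)

    def test_kfold_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        y = 2 * x + rng.normal(size=12)
        a = kfold_cv(ulra_fit, x.reshape(-1, 1), y, k=5, seed=3)
        b = kfold_cv(ulra_fit, x.reshape(-1, 1), y, k=5, seed=3)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)

    def test_mean_predictor_q2_nonpositive(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10).reshape(-1, 1)
        y = rng.normal(size=10)

        def mean_fit(xt, yt):
            m = float(np.mean(yt))
            return lambda xe: np.full(np.atleast_2d(xe).shape[0], m)

        cv = loo_cv(mean_fit, x, y)
        assert q_squared(cv) <= 0


class TestOutlierPolicy:
    def test_explicit_list_counts(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=52)
        y = 2 * x + rng.normal(size=52)
        ids = [f"s{i}" for i in range(52)]
        _, y2, kept, excl = apply_outlier_policy(
            x, y, OutlierPolicy("explicit_list", ids[:2]), ids
        )
        assert len(y2) == 50 and excl == ids[:2]

    def test_empty_policy_is_identity(self):
        x = np.arange(10.0)
        y = 2 * x
        x2, y2, kept, excl = apply_outlier_policy(x, y, OutlierPolicy())
        assert len(x2) == 10 and excl == []

    def test_planted_outlier_recovered(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 10, 30)
        y = 3 * x + 1 + rng.normal(0, 0.5, 30)
        y[17] += 25.0  # gross outlier
        _, _, kept, excl = apply_outlier_policy(
            x, y, OutlierPolicy("studentized_residual", threshold=3.0)
        )
        assert excl == [17]

    def test_refuses_to_empty_dataset(self):
        x = np.arange(4.0)
        y = 2 * x
        with pytest.raises(ValueError):
            apply_outlier_policy(x, y, OutlierPolicy("explicit_list", [0, 1]))
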