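import numpy as np
import pytest

from algaftir.opls import (
    cross_validate_opls,
    fit_opls,
    loading_correlations,
    predict_opls,
    predictive_scores,
    select_components,
)

# --------------------------------------------------------------------------
# Independent PLS oracle: textbook NIPALS, written against the published
# algorithm and sharing no code with the implementation under test.
# --------------------------------------------------------------------------


def oracle_pls2_predict(X, Y, X_new, n_comp):
    """Plain NIPALS PLS2 (X centred, Y centred + unit variance)."""
    x_mean = X.mean(axis=0)
    y_mean, y_sd = Y.mean(axis=0), Y.std(axis=0, ddof=1)
    Xd = X - x_mean
    Yd = (Y - y_mean) / y_sd
    W, P, C = [], [], []
    for _ in range(n_comp):
        u = Yd[:, int(np.argmax(np.var(Yd, axis=0)))].copy()
        for _ in range(10000):
            w = Xd.T @ u
            w = w / np.linalg.norm(w)
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u_new = Yd @ c / (c @ c)
            if np.linalg.norm(u_new - u) < 1e-14 * max(1, np.linalg.norm(u_new)):
                u = u_new
                break
            u = u_new
        p = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        W.append(w), P.append(p), C.append(c)
    W, P, C = (np.array(M).T for M in (W, P, C))
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return ((X_new - x_mean) @ B) * y_sd + y_mean


@pytest.fixture
def random_xy():
    rng = np.random.default_rng(30)
    X = rng.normal(size=(28, 35))
    Y = X @ rng.normal(size=(35, 3)) + 0.5 * rng.normal(size=(28, 3))
    return X, Y


class TestPls2Equivalence:
    @pytest.mark.parametrize("n_comp", [1, 2, 3])
    def test_zero_orthogonal_equals_pls2_oracle(self, random_xy, n_comp):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=n_comp)
        np.testing.assert_allclose(
            predict_opls(m, X), oracle_pls2_predict(X, Y, X, n_comp), atol=1e-8
        )

    def test_single_y_equals_pls1_oracle(self, random_xy):
        X, Y = random_xy
        y = Y[:, :1]
        m = fit_opls(X, y, n_pred=2)
        np.testing.assert_allclose(
            predict_opls(m, X), oracle_pls2_predict(X, y, X, 2), atol=1e-8
        )

    def test_sklearn_cross_check(self, random_xy):
        # looser tolerance: sklearn's NIPALS stops on its own criterion
        from sklearn.cross_decomposition import PLSRegression

        X, Y = random_xy
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        sk = PLSRegression(n_components=2, scale=False, tol=1e-10, max_iter=5000)
        sk.fit(X - X.mean(0), Ys)
        yhat_sk = sk.predict(X - X.mean(0)) * Y.std(0, ddof=1) + Y.mean(0)
        m = fit_opls(X, Y, n_pred=2)
        np.testing.assert_allclose(predict_opls(m, X), yhat_sk, atol=1e-4)


class TestFitOpls:
    def test_exact_fit_on_low_rank_noiseless(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(25, 3)) @ rng.normal(size=(3, 40))
        Y = X @ rng.normal(size=(40, 3))
        m = fit_opls(X, Y, n_pred=3)
        assert m.r2y_cum == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_confound_removed(self):
        rng = np.random.default_rng(32)
        n, p = 40, 60
        Xc = rng.normal(size=(n, 3)) @ rng.normal(size=(3, p))
        Y = Xc @ rng.normal(size=(p, 2))
        confound = np.outer(rng.normal(size=n), rng.normal(size=p))
        clean = fit_opls(Xc, Y, n_pred=1)
        dirty = fit_opls(Xc + 3 * confound, Y, n_pred=1, n_ortho_x=1)
        cos = abs(clean.W[:, 0] @ dirty.W[:, 0])
        assert cos > 0.999

    def test_predictive_scores_orthogonal_to_ortho_scores(self, random_xy):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=2, n_ortho_x=2, n_ortho_y=1)
        assert np.abs(m.T.T @ m.T_ortho).max() < 1e-8

    def test_r2y_nondecreasing_in_components(self, random_xy):
        X, Y = random_xy
        r2 = [fit_opls(X, Y, n_pred=a).r2y_cum for a in (1, 2, 3)]
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 1e-12

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(33)
        with pytest.raises(ValueError):
            fit_opls(rng.normal(size=(5, 10)), rng.normal(size=(5, 3)),
                     n_pred=2, n_ortho_x=2, n_ortho_y=1)


class TestPredictOpls:
    def test_reproduces_calibration_fit(self, random_xy):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=2, n_ortho_x=1)
        a = predict_opls(m, X)
        b = predict_opls(m, X.copy())
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_mean_spectrum_predicts_mean_y(self, random_xy):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=2, n_ortho_x=1, n_ortho_y=1)
        pred = predict_opls(m, X.mean(axis=0))
        np.testing.assert_allclose(pred.ravel(), Y.mean(axis=0), atol=1e-8)

    def test_grid_mismatch_rejected(self, random_xy):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=2)
        with pytest.raises(ValueError, match="wavenumbers"):
            predict_opls(m, X[:, :-1])


class TestSelectComponents:
    def test_pure_noise_selects_minimal_model(self):
        rng = np.random.default_rng(34)
        X = rng.normal(size=(40, 30))
        Y = rng.normal(size=(40, 3))
        (n_pred, n_ox, n_oy), traj = select_components(X, Y, k=5, seed=0)
        assert (n_pred, n_ox, n_oy) == (1, 0, 0)
        assert traj[0][1] <= 0  # Q2 of noise is non-positive

    def test_rank2_relation_selects_two_predictive(self):
        rng = np.random.default_rng(35)
        scores = rng.normal(size=(60, 2))
        X = scores @ rng.normal(size=(2, 30)) + 0.01 * rng.normal(size=(60, 30))
        Y = scores @ rng.normal(size=(2, 3)) + 0.01 * rng.normal(size=(60, 3))
        (n_pred, _, _), _ = select_components(X, Y, k=5, seed=0)
        assert n_pred == 2

    def test_deterministic_given_seed(self, random_xy):
        X, Y = random_xy
        a = select_components(X, Y, max_pred=3, max_ox=1, max_oy=1, k=5, seed=4)
        b = select_components(X, Y, max_pred=3, max_ox=1, max_oy=1, k=5, seed=4)
        assert a == b


class TestLoadingCorrelations:
    def test_column_equal_to_score_gives_one(self, random_xy):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=1)
        X_aug = np.column_stack([X, m.T[:, 0]])
        m2 = fit_opls(X_aug, Y, n_pred=1)
        corr, flags = loading_correlations(m2, X_aug)
        assert corr[0, -1] > 0.999 or corr[0, -1] < -0.999
        assert not flags[-1]

    def test_constant_column_flagged_zero(self, random_xy):
        X, Y = random_xy
        X_aug = np.column_stack([X, np.full(X.shape[0], 3.0)])
        m = fit_opls(X_aug, Y, n_pred=1)
        corr, flags = loading_correlations(m, X_aug)
        assert flags[-1] and corr[0, -1] == 0.0

    def test_bounded(self, random_xy):
        X, Y = random_xy
        m = fit_opls(X, Y, n_pred=2, n_ortho_x=1)
        corr, _ = loading_correlations(m, X)
        assert np.all(corr <= 1.0) and np.all(corr >= -1.0)


class TestCrossValidation:
    def test_q2_near_one_for_strong_relation(self):
        rng = np.random.default_rng(36)
        X = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 20))
        Y = X @ rng.normal(size=(20, 3))
        _, q2 = cross_validate_opls(X, Y, 3, 0, 0, k=5, seed=0)
        assert q2 > 0.999

    def test_scores_projection_matches_training_scores(self):
        rng = np.random.default_rng(37)
        X = rng.normal(size=(30, 25))
        Y = X @ rng.normal(size=(25, 3)) + rng.normal(size=(30, 3))
        m = fit_opls(X, Y, n_pred=2, n_ortho_x=1)
        np.testing.assert_allclose(predictive_scores(m, X), m.T, atol=1e-8)
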