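import numpy as np
import pytest

from nirferm.plsr import (
    PLSRError,
    compute_vip,
    fit_plsr,
    load_model,
    save_model,
    select_n_components,
)


def random_problem(n=30, p=10, n_informative=3, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:n_informative] = rng.normal(size=n_informative)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFitting:
    def test_single_column_matches_ols_slope(self, rng):
        x = rng.normal(size=(20, 1))
        y = 1.7 * x[:, 0] + 0.3 + 0.05 * rng.normal(size=20)
        xc, yc = x[:, 0] - x.mean(), y - y.mean()
        ols_slope = float(xc @ yc / (xc @ xc))
        model = fit_plsr(x, y, 1)
        assert abs(model.coef[0] - ols_slope) < 1e-10

    def test_exact_linear_relation_recovered(self, rng):
        # orthogonal design: the first weight vector aligns with the one
        # informative column, so a single component fits exactly
        Z = rng.normal(size=(25, 12))
        Q, _ = np.linalg.qr(Z - Z.mean(axis=0))  # zero-mean orthonormal columns
        X = Q * np.sqrt(25)
        y = 2.0 * X[:, 7]
        model = fit_plsr(X, y, 1)
        resid = model.predict(X) - y
        assert np.sqrt(np.mean(resid**2)) < 1e-10

    def test_full_rank_equals_least_squares(self):
        # at A = rank(X) the PLS solution coincides with OLS
        rng = np.random.default_rng(123)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, 4)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.coef, beta_ols, atol=1e-8)

    def test_agrees_with_sklearn_pls(self):
        # independent implementation cross-check
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_problem(seed=5)
        ours = fit_plsr(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)
        np.testing.assert_allclose(
            ours.predict(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_scores_are_orthogonal(self):
        X, y = random_problem(n=40, p=15, seed=2)
        model = fit_plsr(X, y, 5)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_weights_are_unit_norm(self):
        X, y = random_problem(seed=3)
        model = fit_plsr(X, y, 4)
        np.testing.assert_allclose(
            np.linalg.norm(model.x_weights, axis=0), 1.0, atol=1e-10
        )

    def test_in_sample_rmse_non_increasing_in_components(self):
        X, y = random_problem(n=40, p=15, n_informative=8, seed=4)
        rmses = []
        for a in range(1, 9):
            model = fit_plsr(X, y, a)
            resid = model.predict(X) - y
            rmses.append(np.sqrt(np.mean(resid**2)))
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_prediction_reproduces_score_space_regression(self):
        X, y = random_problem(seed=6)
        model = fit_plsr(X, y, 3)
        via_scores = model.x_scores @ model.y_loadings + model.y_mean
        np.testing.assert_allclose(model.predict(X), via_scores, atol=1e-10)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_components=0),
            dict(n_components=20),  # exceeds min(n-1, p)
        ],
    )
    def test_component_bounds_enforced(self, bad):
        X, y = random_problem(n=10, p=4)
        with pytest.raises(PLSRError):
            fit_plsr(X, y, **bad)

    def test_zero_variance_y_rejected(self):
        X, _ = random_problem()
        with pytest.raises(PLSRError, match="variance"):
            fit_plsr(X, np.ones(X.shape[0]), 2)

    def test_non_finite_rejected(self):
        X, y = random_problem()
        X[0, 0] = np.nan
        with pytest.raises(PLSRError, match="finite"):
            fit_plsr(X, y, 2)


class TestPrediction:
    def test_mean_spectrum_predicts_mean_response(self):
        X, y = random_problem(seed=8)
        model = fit_plsr(X, y, 3)
        yhat = model.predict(X.mean(axis=0))
        assert abs(yhat[0] - y.mean()) < 1e-10

    def test_constant_shift_moves_prediction_by_coef_sum(self):
        X, y = random_problem(seed=9)
        model = fit_plsr(X, y, 3)
        c = 0.37
        shift = model.predict(X + c) - model.predict(X)
        np.testing.assert_allclose(shift, c * model.coef.sum(), atol=1e-10)

    def test_wavelength_count_mismatch_rejected(self):
        X, y = random_problem()
        model = fit_plsr(X, y, 2)
        with pytest.raises(PLSRError, match="wavelengths"):
            model.predict(X[:, :-1])


class TestVIP:
    def test_single_variable_is_one(self, rng):
        x = rng.normal(size=(15, 1))
        y = 2 * x[:, 0] + 0.1 * rng.normal(size=15)
        vip = compute_vip(fit_plsr(x, y, 1))
        np.testing.assert_allclose(vip.vip, [1.0], atol=1e-12)

    def test_identical_predictors_share_importance(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        y = x[:, 0] + 0.05 * rng.normal(size=20)
        vip = compute_vip(fit_plsr(X, y, 1))
        np.testing.assert_allclose(vip.vip, [1.0, 1.0], atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_squared_scores_sum_to_p(self, seed):
        X, y = random_problem(n=25, p=11, seed=seed)
        model = fit_plsr(X, y, 1 + seed % 5)
        vip = compute_vip(model)
        assert abs(np.sum(vip.vip**2) - X.shape[1]) < 1e-8
        assert np.all(vip.vip >= 0)

    def test_max_vip_at_least_one(self):
        # sum v_j^2 = p forces the largest score to reach 1
        X, y = random_problem(n=30, p=9, seed=11)
        vip = compute_vip(fit_plsr(X, y, 3))
        assert vip.vip.max() >= 1.0 - 1e-10


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = random_problem(seed=12)
        model = fit_plsr(X, y, 3)
        path = tmp_path / "model.txt"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-12)
        np.testing.assert_allclose(back.ss, model.ss, atol=1e-12)


class TestComponentSelection:
    def test_choice_minimises_cross_validated_press(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(60, 10))
        y = X[:, 0] - 2 * X[:, 1] + 0.5 * rng.normal(size=60)
        a = select_n_components(X, y, max_components=6, seed=0)
        assert 1 <= a <= 6
        # deterministic under the same seed
        assert a == select_n_components(X, y, max_components=6, seed=0)
        # a single component underfits this two-direction signal
        assert a >= 2
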