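"""SVR, EM-RVR and GPR fits against closed-form and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import brainage as ba
from brainage.cohort import ParameterError
from brainage.preprocessing import DataError
from brainage.regressors import DegenerateRVRError, svr_objective


class TestSVR:
    def test_noiseless_line_recovered(self, rng):
        x = rng.normal(size=(60, 1))
        y = 3.0 * x[:, 0]
        tm = ba.fit_svr(x, y, ba.SVRConfig(C=1e4, max_iter=50_000))
        assert tm.weights[0] == pytest.approx(3.0, abs=1e-3)
        assert np.mean(np.abs(tm.predict(x) - y)) < 1e-3

    def test_vanishing_c_shrinks_weights(self, rng):
        x = rng.normal(size=(50, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 60
        tm = ba.fit_svr(x, y, ba.SVRConfig(C=1e-8))
        assert np.max(np.abs(tm.weights)) < 1e-3
        assert np.allclose(tm.predict(x), tm.intercept, atol=1e-3)

    def test_local_optimality_against_perturbations(self, rng):
        # brute-force oracle: the returned solution should beat 1,000 random
        # weight perturbations on the primal epsilon-insensitive objective
        x = rng.normal(size=(50, 3))
        y = x @ np.array([0.5, 1.5, -1.0]) + rng.normal(0, 0.3, 50)
        cfg = ba.SVRConfig(C=1.0, max_iter=100_000, tol=1e-8)
        tm = ba.fit_svr(x, y, cfg)
        j_star = svr_objective(x, y, tm.weights, tm.intercept, C=1.0)
        scale = 0.05 * (1.0 + np.abs(tm.weights))
        for _ in range(1000):
            w = tm.weights + rng.normal(0, 1, 3) * scale
            assert svr_objective(x, y, w, tm.intercept, C=1.0) >= j_star - 1e-9

    def test_precomputed_collapse_matches_dual_predictions(self, rng):
        x = rng.normal(size=(40, 6))
        y = x @ rng.normal(size=6) + 55
        gram = x @ x.T
        tm = ba.fit_svr(gram, y, ba.SVRConfig(kernel="precomputed", C=2.0), features=x)
        x_new = rng.normal(size=(15, 6))
        from sklearn.svm import SVR as SkSVR

        ref = SkSVR(kernel="precomputed", C=2.0, epsilon=0.0, tol=1e-4, max_iter=1000)
        ref.fit(gram, y)
        assert np.allclose(tm.predict(x_new), ref.predict(x_new @ x.T), atol=1e-8)

    def test_nonfinite_inputs_rejected(self):
        x = np.array([[1.0], [np.nan]])
        with pytest.raises(DataError):
            ba.fit_svr(x, np.array([1.0, 2.0]))

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            ba.SVRConfig(C=-1.0)
        with pytest.raises(ParameterError):
            ba.SVRConfig(epsilon=-0.1)


class TestRVR:
    def test_noiseless_line_interpolated(self, rng):
        x = rng.normal(size=(40, 1))
        y = 2.0 * x[:, 0]
        fit, tm = ba.fit_rvr(x, y, ba.RVRConfig(tol=1e-6))
        assert np.mean(np.abs(tm.predict(x) - y)) < 1e-6
        assert fit.n_relevance_vectors <= 40

    def test_fixed_precision_posterior_is_ridge(self, rng):
        # closed-form oracle: at fixed alpha and beta, the posterior mean is
        # ridge regression with penalty alpha/beta
        phi = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        alpha, beta = 2.5, 4.0
        mu, _ = ba.rvr_posterior(phi, y, np.full(8, alpha), beta)
        ridge = np.linalg.solve(phi.T @ phi + (alpha / beta) * np.eye(8), phi.T @ y)
        assert np.allclose(mu, ridge, atol=1e-10)

    def test_pure_noise_underfits_and_predicts_mean(self):
        # mirrors the underfitting observed with weak-signal training data
        n_under, devs = 0, []
        for seed in range(50):
            g = np.random.default_rng(seed)
            x = g.normal(size=(40, 6))
            y = 60 + g.normal(0, 5, 40)
            try:
                fit, tm = ba.fit_rvr(x, y)
            except DegenerateRVRError:
                n_under += 1
                devs.append(0.0)
                continue
            if fit.underfit:
                n_under += 1
                devs.append(float(np.mean(np.abs(tm.predict(x) - y.mean()))))
        assert n_under > 0
        assert np.mean(devs) < 2.0  # flagged fits hug the training mean age

    def test_sparsity_non_increasing(self, rng):
        age = rng.integers(47, 74, 120).astype(float)
        x = np.outer(age - 60, rng.normal(size=10) * 0.3) + rng.normal(size=(120, 10))
        fit, _ = ba.fit_rvr(x, age)
        assert all(a >= b for a, b in zip(fit.rv_history, fit.rv_history[1:]))

    def test_constant_target_degenerates_to_mean(self, rng):
        with pytest.raises(DegenerateRVRError) as err:
            ba.fit_rvr(rng.normal(size=(20, 3)), np.full(20, 61.0))
        assert err.value.fallback_mean == pytest.approx(61.0)

    def test_precomputed_kernel_matches_linear(self, rng):
        x = rng.normal(size=(50, 5))
        y = x @ rng.normal(size=5) + 60 + rng.normal(0, 0.5, 50)
        _, tm_lin = ba.fit_rvr(x, y)
        _, tm_pre = ba.fit_rvr(
            x @ x.T, y, ba.RVRConfig(kernel="precomputed"), features=x
        )
        x_new = rng.normal(size=(10, 5))
        assert np.allclose(tm_lin.predict(x_new), tm_pre.predict(x_new), atol=1e-6)

    def test_underfit_threshold_scales_with_n(self):
        fit = ba.RVRFit(
            mu=np.zeros(1), sigma=np.zeros((1, 1)), active=np.arange(50),
            alpha=np.zeros(1), beta=1.0, n_train=9432, n_iter=1, converged=True,
        )
        assert fit.underfit_threshold == 600
        assert fit.underfit  # 50 relevance vectors out of 9,432 is underfitted
        small = ba.RVRFit(
            mu=np.zeros(1), sigma=np.zeros((1, 1)), active=np.arange(50),
            alpha=np.zeros(1), beta=1.0, n_train=100, n_iter=1, converged=True,
        )
        assert small.underfit_threshold == 7
        assert not small.underfit


class TestGPR:
    def test_matches_bayesian_linear_regression(self, rng):
        # closed-form oracle: dot-product-kernel GPR posterior mean equals
        # Bayesian linear regression with a sigma_0-augmented design
        x = rng.normal(size=(40, 4))
        y = x @ rng.normal(size=4) + 2 + rng.normal(0, 0.5, 40)
        sigma0, jitter = 1.3, 1e-4
        tm = ba.fit_gpr(x, y, ba.GPRConfig(sigma_0=sigma0, optimise=False, jitter=jitter))
        x_new = rng.normal(size=(12, 4))
        phi = np.column_stack([np.full(40, sigma0), x])
        phi_new = np.column_stack([np.full(12, sigma0), x_new])
        a = phi.T @ phi + jitter * np.eye(5)
        blr = phi_new @ np.linalg.solve(a, phi.T @ y)
        assert np.allclose(tm.predict(x_new), blr, atol=1e-8)

    def test_interpolates_training_points_at_small_jitter(self, rng):
        x = rng.normal(size=(25, 30))
        y = 60 + rng.normal(0, 3, 25)
        tm = ba.fit_gpr(x, y, ba.GPRConfig(optimise=False, jitter=1e-10))
        assert np.max(np.abs(tm.predict(x) - y)) < 1e-4

    def test_uncertainty_grows_away_from_data(self, rng):
        x = rng.normal(size=(30, 3))
        y = x @ np.ones(3) + 60
        tm = ba.fit_gpr(x, y, ba.GPRConfig(optimise=False))
        _, var_train = ba.predict_with_uncertainty(tm, x)
        _, var_far = ba.predict_with_uncertainty(tm, 100.0 * np.ones((1, 3)))
        assert var_far[0] > var_train.max()

    def test_uncertainty_requires_gpr(self, rng):
        tm = ba.fit_svr(rng.normal(size=(20, 2)), rng.normal(size=20))
        with pytest.raises(ParameterError):
            ba.predict_with_uncertainty(tm, np.zeros((1, 2)))


class TestTrainedModel:
    def test_linear_rescaling_invariance(self, rng):
        # doubling a feature's scale while halving its weight leaves the
        # linear prediction unchanged
        x = rng.normal(size=(20, 3))
        w = np.array([1.0, -0.5, 2.0])
        tm = ba.TrainedModel(kind="svr", weights=w, intercept=60.0)
        x2 = x.copy()
        x2[:, 1] *= 2.0
        tm2 = ba.TrainedModel(
            kind="svr", weights=w * np.array([1.0, 0.5, 1.0]), intercept=60.0
        )
        assert np.allclose(tm.predict(x), tm2.predict(x2))

    def test_dimension_mismatch(self, rng):
        tm = ba.TrainedModel(kind="svr", weights=np.ones(3), intercept=0.0)
        with pytest.raises(DataError):
            tm.predict(rng.normal(size=(4, 5)))
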