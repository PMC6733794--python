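"""State-space core: simulation moments, filter vs joint-Gaussian
oracle, smoother conditioning oracle, EM properties, forecasting."""
import numpy as np
import pytest
from scipy.stats import multivariate_normal

from slwarn import (
    GaussianRandomWalkSSM,
    SSMParams,
    em_fit,
    forecast,
    kalman_filter,
    kalman_smooth,
    simulate,
)
from conftest import random_params


def stacked_moments(params, T):
    """Mean/covariance of the stacked observation vector (oracle).

    x_t = x_0 + sum_{s<=t} w_s gives Cov(x_s, x_t) = Lambda + min(s,t) Q
    (1-based t), hence closed-form joint Gaussian moments for y.
    """
    n, e = params.n, params.e
    Z, Q, R, Lam = params.Z, params.Q, params.R, params.Lambda
    mean = np.tile(Z @ params.pi + params.a, T)
    cov = np.zeros((n * T, n * T))
    for s in range(T):
        for t in range(T):
            blk = Z @ (Lam + min(s + 1, t + 1) * Q) @ Z.T
            if s == t:
                blk = blk + R
            cov[s * n : (s + 1) * n, t * n : (t + 1) * n] = blk
    return mean, cov


class TestSimulate:
    def test_noiseless_constant(self):
        p = SSMParams(
            Z=np.array([[2.0], [1.0]]), a=np.array([1.0, -1.0]),
            Q=np.zeros((1, 1)), R=np.zeros((2, 2)),
            pi=np.array([3.0]), Lambda=np.zeros((1, 1)),
        )
        _, y = simulate(p, 5, seed=0)
        np.testing.assert_allclose(y, np.tile([[7.0], [2.0]], 5))

    def test_increment_variance_matches_moment_identity(self):
        # e=1, Z=1, a=0: Var(y_t - y_{t-1}) = Q + 2R
        q, r = 0.7, 0.4
        p = SSMParams(Z=np.ones((1, 1)), a=np.zeros(1), Q=q * np.eye(1),
                      R=r * np.eye(1), pi=np.zeros(1), Lambda=np.eye(1))
        _, y = simulate(p, 100_000, seed=3)
        v = np.diff(y[0]).var()
        assert v == pytest.approx(q + 2 * r, rel=0.03)

    def test_seed_reproducibility(self):
        p = SSMParams(Z=np.ones((2, 1)), a=np.zeros(2), Q=np.eye(1),
                      R=np.eye(2), pi=np.zeros(1), Lambda=np.eye(1))
        x1, y1 = simulate(p, 20, seed=42)
        x2, y2 = simulate(p, 20, seed=42)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(x1, x2)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            SSMParams(Z=np.ones((1, 1)), a=np.zeros(1),
                      Q=-np.eye(1), R=np.eye(1), pi=np.zeros(1), Lambda=np.eye(1))


class TestFilter:
    def test_loglik_matches_joint_gaussian_oracle(self, rng):
        p = random_params(rng, n=2, e=1)
        _, y = simulate(p, 6, seed=7)
        f = kalman_filter(p, y)
        mean, cov = stacked_moments(p, 6)
        ll = multivariate_normal.logpdf(y.T.ravel(), mean, cov)
        assert f.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_loglik_oracle_property_random_instances(self, rng):
        for k in range(30):
            n = int(rng.integers(1, 4))
            e = int(rng.integers(1, min(n, 2) + 1))
            T = int(rng.integers(2, 9))
            p = random_params(rng, n, e)
            _, y = simulate(p, T, seed=k)
            f = kalman_filter(p, y)
            mean, cov = stacked_moments(p, T)
            ll = multivariate_normal.logpdf(y.T.ravel(), mean, cov)
            assert abs(f.log_likelihood - ll) < 1e-7

    def test_exact_observation_limit(self, rng):
        # R -> 0, Z = I: filtered mean reproduces y - a
        n = 2
        p = SSMParams(Z=np.eye(n), a=np.array([1.0, -2.0]), Q=np.eye(n),
                      R=1e-12 * np.eye(n), pi=np.zeros(n), Lambda=np.eye(n))
        y = rng.normal(size=(n, 10))
        f = kalman_filter(p, y)
        np.testing.assert_allclose(f.filtered_means, y - p.a[:, None], atol=1e-4)

    def test_steady_state_gain_is_riccati_fixed_point(self):
        # univariate local level, Q = R = 1, diffuse start: iterate the
        # scalar Riccati recursion to its fixed point independently
        P = 1e6
        for _ in range(200):
            Pp = P + 1.0
            K = Pp / (Pp + 1.0)
            P = (1 - K) * Pp
        p = SSMParams(Z=np.eye(1), a=np.zeros(1), Q=np.eye(1), R=np.eye(1),
                      pi=np.zeros(1), Lambda=1e6 * np.eye(1))
        y = np.random.default_rng(0).normal(size=(1, 300))
        f = kalman_filter(p, y)
        Pp_last = f.predicted_covs[-1, 0, 0]
        K_last = Pp_last / (Pp_last + 1.0)
        assert K_last == pytest.approx(K, abs=1e-9)
        # the fixed-point gain is the golden-ratio value (sqrt(5)-1)/2
        assert K == pytest.approx((np.sqrt(5) - 1) / 2, abs=1e-9)

    def test_covariances_symmetric_psd(self, rng):
        p = random_params(rng, 3, 2)
        _, y = simulate(p, 15, seed=1)
        f = kalman_smooth(kalman_filter(p, y), p)
        for covs in (f.predicted_covs, f.filtered_covs, f.smoothed_covs):
            for C in covs:
                np.testing.assert_allclose(C, C.T, atol=1e-10)
                assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_row_permutation_equivariance(self, rng):
        p = random_params(rng, 3, 1)
        _, y = simulate(p, 12, seed=5)
        perm = np.array([2, 0, 1])
        p2 = SSMParams(Z=p.Z[perm], a=p.a[perm], Q=p.Q,
                       R=p.R[np.ix_(perm, perm)], pi=p.pi, Lambda=p.Lambda)
        f1 = kalman_filter(p, y)
        f2 = kalman_filter(p2, y[perm])
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-9)
        np.testing.assert_allclose(f1.filtered_means, f2.filtered_means, atol=1e-9)


class TestSmoother:
    def test_single_step_equals_filter(self, rng):
        p = random_params(rng, 2, 1)
        _, y = simulate(p, 1, seed=0)
        f = kalman_smooth(kalman_filter(p, y), p)
        np.testing.assert_allclose(f.smoothed_means, f.filtered_means)
        np.testing.assert_allclose(f.smoothed_covs, f.filtered_covs)

    def test_degenerate_random_walk_gives_constant_state(self, rng):
        p = SSMParams(Z=np.array([[1.0], [0.5]]), a=np.zeros(2),
                      Q=np.zeros((1, 1)), R=np.eye(2),
                      pi=np.zeros(1), Lambda=np.eye(1))
        _, y = simulate(p, 10, seed=2)
        f = kalman_smooth(kalman_filter(p, y), p)
        assert np.ptp(f.smoothed_means[0]) < 1e-10

    def test_matches_joint_gaussian_conditioning(self, rng):
        # smoothed mean = E[x | all y] from the joint Gaussian of (x, y)
        p = random_params(rng, 2, 1)
        T = 5
        _, y = simulate(p, T, seed=9)
        f = kalman_smooth(kalman_filter(p, y), p)
        n, e = p.n, p.e
        # joint covariance of stacked states and observations
        Cx = np.zeros((e * T, e * T))
        for s in range(T):
            for t in range(T):
                Cx[s * e : (s + 1) * e, t * e : (t + 1) * e] = (
                    p.Lambda + min(s + 1, t + 1) * p.Q
                )
        Zb = np.kron(np.eye(T), p.Z)
        Cy = Zb @ Cx @ Zb.T + np.kron(np.eye(T), p.R)
        Cxy = Cx @ Zb.T
        mx = np.tile(p.pi, T)
        my = np.tile(p.Z @ p.pi + p.a, T)
        cond = mx + Cxy @ np.linalg.solve(Cy, y.T.ravel() - my)
        np.testing.assert_allclose(f.smoothed_means.T.ravel(), cond, atol=1e-8)
        cond_cov = Cx - Cxy @ np.linalg.solve(Cy, Cxy.T)
        for t in range(T):
            np.testing.assert_allclose(
                f.smoothed_covs[t], cond_cov[t * e : (t + 1) * e, t * e : (t + 1) * e],
                atol=1e-8,
            )

    def test_smoothing_never_inflates_covariance(self, rng):
        p = random_params(rng, 3, 2)
        _, y = simulate(p, 20, seed=4)
        f = kalman_smooth(kalman_filter(p, y), p)
        for t in range(20):
            gap = f.filtered_covs[t] - f.smoothed_covs[t]
            assert np.linalg.eigvalsh(gap).min() > -1e-8


class TestEM:
    def test_monotone_loglik_random_instances(self, rng):
        for k in range(20):
            n = int(rng.integers(1, 5))
            e = int(rng.integers(1, min(n, 2) + 1))
            p = random_params(rng, n, e)
            _, y = simulate(p, 30, seed=100 + k)
            fit = em_fit(y, e=e, max_iter=40)
            d = np.diff(fit.loglik_trace)
            assert (d > -1e-9 * np.maximum(1.0, np.abs(fit.loglik_trace[:-1]))).all()

    def test_constant_input_handled(self):
        y = np.full((2, 30), 3.5)
        fit = em_fit(y, e=1)
        np.testing.assert_allclose(fit.params.a, 3.5)
        assert np.isfinite(fit.loglik_trace).all()
        assert fit.converged

    def test_parameter_recovery_single_trend(self):
        truthZ = np.array([1.0, 0.8, 0.6, -0.4, 0.5, -0.7])
        truthR = np.array([0.3, 0.5, 0.7, 0.9, 1.1, 0.4])
        p = SSMParams(Z=truthZ[:, None], a=np.zeros(6), Q=np.eye(1),
                      R=np.diag(truthR), pi=np.zeros(1), Lambda=np.eye(1))
        _, y = simulate(p, 500, seed=11)
        fit = em_fit(y, e=1)
        Zh = fit.params.Z.ravel()
        Zh = Zh * np.sign(Zh @ truthZ)  # sign indeterminacy
        assert np.abs(Zh - truthZ).max() < 0.15
        assert np.abs(np.diag(fit.params.R) / truthR - 1).max() < 0.25

    def test_identifiability_constraints_enforced(self, rng):
        y = rng.normal(size=(4, 60))
        fit = em_fit(y, e=2, max_iter=30)
        p = fit.params
        np.testing.assert_allclose(p.Q, np.eye(2))
        assert p.Z[0, 1] == 0.0  # upper triangle of first e rows
        off_diag = p.R - np.diag(np.diag(p.R))
        np.testing.assert_array_equal(off_diag, 0.0)
        np.testing.assert_array_equal(p.pi, 0.0)

    def test_offset_profiled_as_window_mean(self, rng):
        y = rng.normal(size=(3, 40)) + np.array([[5.0], [-2.0], [0.5]])
        fit = em_fit(y, e=1, max_iter=30)
        np.testing.assert_allclose(fit.params.a, y.mean(axis=1))

    def test_nonconvergence_flagged_with_warning(self, rng):
        p = random_params(rng, 4, 2)
        _, y = simulate(p, 60, seed=0)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = em_fit(y, e=2, max_iter=2)
        assert not fit.converged


class TestForecast:
    def test_covariance_identity_at_zero_uncertainty(self, rng):
        p = random_params(rng, 2, 1)
        _, y = simulate(p, 10, seed=1)
        f = kalman_filter(p, y)
        f.filtered_covs[5] = 0.0
        p0 = SSMParams(Z=p.Z, a=p.a, Q=np.zeros((1, 1)), R=p.R,
                       pi=p.pi, Lambda=p.Lambda)
        _, F = forecast(p0, f, t=5, lam=1)
        np.testing.assert_allclose(F, p.R, atol=1e-12)

    def test_covariance_linear_in_horizon(self, rng):
        p = random_params(rng, 3, 2)
        _, y = simulate(p, 10, seed=2)
        f = kalman_filter(p, y)
        _, F1 = forecast(p, f, t=9, lam=1)
        _, F2 = forecast(p, f, t=9, lam=2)
        np.testing.assert_allclose(F2 - F1, p.Z @ p.Q @ p.Z.T, atol=1e-10)

    def test_matches_monte_carlo_propagation(self, rng):
        p = random_params(rng, 2, 1)
        _, y = simulate(p, 30, seed=3)
        f = kalman_filter(p, y)
        t, lam = 29, 3
        mean, F = forecast(p, f, t=t, lam=lam)
        # propagate draws from the filtered posterior through the model
        B = 100_000
        Lp = np.linalg.cholesky(f.filtered_covs[t] + 1e-12 * np.eye(p.e))
        x = f.filtered_means[:, t][None, :] + rng.standard_normal((B, p.e)) @ Lp.T
        Lq = np.linalg.cholesky(p.Q)
        for _ in range(lam):
            x = x + rng.standard_normal((B, p.e)) @ Lq.T
        Lr = np.linalg.cholesky(p.R)
        ysim = x @ p.Z.T + p.a + rng.standard_normal((B, p.n)) @ Lr.T
        se_mean = np.sqrt(np.diag(F) / B)
        assert np.all(np.abs(ysim.mean(axis=0) - mean) < 4 * se_mean)
        np.testing.assert_allclose(np.cov(ysim.T), F, rtol=0.05, atol=0.05)


class TestEstimator:
    def test_sklearn_contract(self):
        est = GaussianRandomWalkSSM(n_trends=2, max_iter=10)
        assert est.get_params()["n_trends"] == 2
        est.set_params(n_trends=1)
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(50, 3))
        est.fit(Y)
        assert est.loadings_.shape == (3, 1)
        assert est.obs_variances_.shape == (3,)
        assert np.isfinite(est.score(Y))

    def test_roundtrip_forecast_rmse_approaches_steady_state_floor(self):
        # simulate -> fit -> 1-step forecasts on held-out data: the mean
        # squared error approaches tr(Z (P_inf + Q) Z' + R)/n where
        # P_inf is the steady-state filtered covariance (Riccati fixed
        # point under the true parameters); it can never fall below the
        # naive floor tr(Z Q Z' + R)/n
        truthZ = np.array([[0.8], [0.6], [-0.5], [0.4]])
        R = np.diag([0.4, 0.6, 0.5, 0.3])
        p = SSMParams(Z=truthZ, a=np.zeros(4), Q=np.eye(1), R=R,
                      pi=np.zeros(1), Lambda=np.eye(1))
        # scalar-state Riccati fixed point via information form
        info = float((truthZ.T @ np.linalg.solve(R, truthZ))[0, 0])
        P = 1.0
        for _ in range(500):
            P = 1.0 / (1.0 / (P + 1.0) + info)
        _, y = simulate(p, 600, seed=21)
        fit = em_fit(y[:, :400], e=1)
        f = kalman_filter(fit.params, y)
        errs = []
        for t in range(400, 599):
            mean, _ = forecast(fit.params, f, t=t, lam=1)
            errs.append(((y[:, t + 1] - mean) ** 2).mean())
        target = np.trace(truthZ @ ((P + 1.0) * np.eye(1)) @ truthZ.T + R) / 4
        floor = np.trace(truthZ @ truthZ.T + R) / 4
        assert np.mean(errs) == pytest.approx(target, rel=0.15)
        assert np.mean(errs) > floor * 0.95
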