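r"""Linear-Gaussian state-space model with random-walk hidden trends.

The model for an ``n``-variable series ``y_t`` with ``e`` hidden trends
``x_t`` (``e << n``)::

    x_t = x_{t-1} + w_t,          w_t ~ MVN(0, Q),   x_0 ~ MVN(pi, Lambda)
    y_t = Z x_t + a + v_t,        v_t ~ MVN(0, R)

The hidden trends stand in for unobserved (e.g. biological) processes;
the observables are noisy linear combinations of them.  Estimation is
EM over a constrained parameter set that makes the factor model
identifiable (the standard dynamic-factor constraints):

* ``Q = I_e`` fixed (trend scale absorbed into ``Z``),
* ``Z[i, j] = 0`` for ``j > i`` in the first ``e`` rows,
* ``R`` diagonal (unequal variances), floored at ``obs_var_floor``,
* ``pi = 0`` fixed, ``Lambda = init_cov_scale * I_e`` fixed (diffuse on
  Z-scored data),
* the offset ``a`` is profiled out by demeaning the data and storing the
  mean (equivalent under the constraints, cheaper and numerically
  stabler).

This module provides exact Kalman filtering/smoothing, the exact
log-likelihood, EM estimation, simulation and :math:`\lambda`-step-ahead
forecasting, plus a scikit-learn estimator wrapper
(:class:`GaussianRandomWalkSSM`).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(_symmetrize(M))
    if w.min(initial=0.0) < -tol * max(1.0, abs(w).max(initial=1.0)):
        raise ValueError(f"{name} must be positive semidefinite (min eig {w.min()})")


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(_symmetrize(np.asarray(M, dtype=float)))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


_potrf, _potrs = sla.get_lapack_funcs(("potrf", "potrs"), (np.empty((1, 1)),))


def _chol_with_jitter(S: np.ndarray, base_jitter: float = 1e-10, tries: int = 3):
    """Lower Cholesky factor of S, retrying with growing diagonal jitter."""
    S = _symmetrize(S)
    jitter = 0.0
    for k in range(tries + 1):
        c, info = _potrf(S + jitter * np.eye(S.shape[0]), lower=1, clean=0, overwrite_a=False)
        if info == 0:
            return c
        jitter = base_jitter * (10.0**k)
    raise np.linalg.LinAlgError(
        "innovation covariance is singular; consider flooring the observation "
        "variances (obs_var_floor) or rescaling the data"
    )


def _chol_solve(c: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve S x = b given the lower Cholesky factor of S."""
    x, info = _potrs(c, b if b.ndim > 1 else b[:, None], lower=1)
    if info != 0:  # pragma: no cover - potrs only fails on bad input
        raise np.linalg.LinAlgError("cholesky solve failed")
    return x if b.ndim > 1 else x[:, 0]


@dataclass
class SSMParams:
    """Parameter set theta = (Z, a, Q, R, pi, Lambda) of the model."""

    Z: np.ndarray  # (n, e) loading matrix
    a: np.ndarray  # (n,) offsets
    Q: np.ndarray  # (e, e) process covariance
    R: np.ndarray  # (n, n) observation covariance
    pi: np.ndarray  # (e,) initial mean of x_0
    Lambda: np.ndarray  # (e, e) initial covariance of x_0

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        n, e = self.Z.shape
        if e > n:
            raise ValueError(f"need e <= n, got e={e}, n={n}")
        if self.a.shape != (n,):
            raise ValueError("a must have shape (n,)")
        if self.Q.shape != (e, e) or self.Lambda.shape != (e, e):
            raise ValueError("Q and Lambda must have shape (e, e)")
        if self.R.shape != (n, n):
            raise ValueError("R must have shape (n, n)")
        if self.pi.shape != (e,):
            raise ValueError("pi must have shape (e,)")
        for M, name in ((self.Q, "Q"), (self.R, "R"), (self.Lambda, "Lambda")):
            _check_psd(M, name)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def e(self) -> int:
        return self.Z.shape[1]


@dataclass
class FilterResult:
    """Kalman filter/smoother output for one series.

    Means are ``(e, T)`` arrays, covariance stacks are ``(T, e, e)``.
    ``smoothed_*`` blocks are None until :func:`kalman_smooth` runs.
    """

    y: np.ndarray
    predicted_means: np.ndarray
    predicted_covs: np.ndarray
    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    innovations: np.ndarray
    innovation_covs: np.ndarray
    log_likelihood: float
    smoothed_means: np.ndarray | None = None
    smoothed_covs: np.ndarray | None = None


@dataclass
class EMFit:
    """Result of :func:`em_fit`."""

    params: SSMParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


def simulate(
    params: SSMParams, T: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw hidden states (e, T) and observations (n, T) from the model."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    e, n = params.e, params.n
    Ls = _psd_sqrt(params.Lambda)
    Lq = _psd_sqrt(params.Q)
    Lr = _psd_sqrt(params.R)
    x0 = params.pi + Ls @ rng.standard_normal(e)
    w = Lq @ rng.standard_normal((e, T))
    x = x0[:, None] + np.cumsum(w, axis=1)
    v = Lr @ rng.standard_normal((n, T))
    y = params.Z @ x + params.a[:, None] + v
    return x, y


def kalman_filter(params: SSMParams, y: np.ndarray) -> FilterResult:
    """Forward recursions for the random-walk-trend model.

    Returns predicted/filtered moments, innovations and the exact
    log-likelihood ``sum_t log N(y_t; Z x_{t|t-1} + a, Z P_{t|t-1} Z' + R)``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, T = y.shape
    if n != params.n:
        raise ValueError(f"y has {n} rows but params expect n={params.n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be complete/finite (impute first)")
    e = params.e
    Z, a, Q, R = params.Z, params.a, params.Q, params.R

    xp = np.empty((e, T))
    Pp = np.empty((T, e, e))
    xf = np.empty((e, T))
    Pf = np.empty((T, e, e))
    innov = np.empty((n, T))
    Scov = np.empty((T, n, n))

    x_pred = params.pi.copy()
    P_pred = _symmetrize(params.Lambda + Q)
    ll = 0.0
    I_e = np.eye(e)
    for t in range(T):
        xp[:, t] = x_pred
        Pp[t] = P_pred
        et = y[:, t] - Z @ x_pred - a
        S = _symmetrize(Z @ P_pred @ Z.T + R)
        c = _chol_with_jitter(S)
        Sinv_e = _chol_solve(c, et)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        ll += -0.5 * (n * _LOG2PI + logdet + et @ Sinv_e)
        K = _chol_solve(c, Z @ P_pred).T  # (e, n)
        x_filt = x_pred + K @ et
        ImKZ = I_e - K @ Z
        P_filt = _symmetrize(ImKZ @ P_pred @ ImKZ.T + K @ R @ K.T)  # Joseph form
        xf[:, t] = x_filt
        Pf[t] = P_filt
        innov[:, t] = et
        Scov[t] = S
        x_pred = x_filt
        P_pred = _symmetrize(P_filt + Q)

    return FilterResult(
        y=y,
        predicted_means=xp,
        predicted_covs=Pp,
        filtered_means=xf,
        filtered_covs=Pf,
        innovations=innov,
        innovation_covs=Scov,
        log_likelihood=float(ll),
    )


def kalman_smooth(filt: FilterResult, params: SSMParams) -> FilterResult:
    """Rauch-Tung-Striebel backward pass (identity state transition)."""
    T = filt.y.shape[1]
    e = params.e
    xs = np.empty((e, T))
    Ps = np.empty((T, e, e))
    xs[:, -1] = filt.filtered_means[:, -1]
    Ps[-1] = filt.filtered_covs[-1]
    for t in range(T - 2, -1, -1):
        Pf = filt.filtered_covs[t]
        Pp_next = filt.predicted_covs[t + 1]
        J = np.linalg.solve(_symmetrize(Pp_next), Pf).T  # Pf @ inv(Pp_next)
        xs[:, t] = filt.filtered_means[:, t] + J @ (xs[:, t + 1] - filt.predicted_means[:, t + 1])
        Ps[t] = _symmetrize(Pf + J @ (Ps[t + 1] - Pp_next) @ J.T)
    return replace(filt, smoothed_means=xs, smoothed_covs=Ps)


def forecast(
    params: SSMParams, filt: FilterResult, t: int, lam: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """lambda-step-ahead forecast of the observables from time index ``t``.

    Under the random-walk transition the mean does not depend on
    ``lam``:  ``yhat = Z x_{t|t} + a``;  the forecast covariance is
    ``F = Z (P_{t|t} + lam * Q) Z' + R``.  ``t + lam`` may point beyond
    the observed range (pure prediction).
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    T = filt.y.shape[1]
    if not 0 <= t < T:
        raise ValueError(f"t={t} outside filtered range [0, {T})")
    x = filt.filtered_means[:, t]
    P = filt.filtered_covs[t]
    mean = params.Z @ x + params.a
    F = _symmetrize(params.Z @ (P + lam * params.Q) @ params.Z.T + params.R)
    return mean, F


def _constrained_row_support(n: int, e: int) -> list[np.ndarray]:
    """Free column indices per row of Z (upper triangle of first e rows fixed 0)."""
    return [np.arange(min(i + 1, e)) for i in range(n)]


def _init_params(
    yd: np.ndarray, e: int, init_cov_scale: float, obs_var_floor: float, rng
) -> SSMParams:
    """Data-driven initial parameters on demeaned data (a = 0).

    With Q = I the loading scale is identified by the increments
    (Var(dy) = Z Z' + 2R), so the init comes from an SVD of the
    differenced series rather than of the levels, whose scale grows
    with the window length under a random-walk trend.
    """
    n, T = yd.shape
    dy = np.diff(yd, axis=1) if T > 1 else yd
    U, s, _ = np.linalg.svd(dy, full_matrices=False)
    k = min(e, s.size)
    Z0 = np.zeros((n, e))
    Z0[:, :k] = U[:, :k] * (s[:k] / np.sqrt(2.0 * max(dy.shape[1], 1)))
    # enforce identifiability zeros; nudge diagonal pivots off zero
    for i in range(min(e, n)):
        Z0[i, i + 1 :] = 0.0
        if abs(Z0[i, i]) < 1e-6:
            Z0[i, i] = 1e-3 if rng is None else 1e-3 * (1 + rng.uniform())
    var = yd.var(axis=1)
    R0 = np.diag(np.maximum(0.5 * var, obs_var_floor))
    return SSMParams(
        Z=Z0,
        a=np.zeros(n),
        Q=np.eye(e),
        R=R0,
        pi=np.zeros(e),
        Lambda=init_cov_scale * np.eye(e),
    )


def em_fit(
    y: np.ndarray,
    e: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed=None,
    init: SSMParams | None = None,
    init_cov_scale: float = 5.0,
    obs_var_floor: float = 1e-8,
) -> EMFit:
    """Constrained EM estimation of (Z, R, a) with Q = I fixed.

    The offset ``a`` is profiled out: the series is demeaned once and
    the row means are stored as ``a``.  Each iteration runs the exact
    E-step (filter + smoother) and the exact M-step for ``Z`` (row-wise
    least squares on the free loadings, which is the constrained argmax
    because ``R`` is diagonal) followed by the exact ``R`` update given
    the new ``Z``.  The log-likelihood trace is therefore non-decreasing
    up to round-off.

    Parameters
    ----------
    y : (n, T) array
        Complete (imputed) window of observations.
    e : int
        Number of hidden trends.
    init : SSMParams, optional
        Warm start (e.g. the previous moving window's fit); ``a`` is
        re-profiled on the current window.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, T = y.shape
    if T < e + 2:
        raise ValueError(f"need T >= e + 2, got T={T}, e={e}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    rng = np.random.default_rng(seed) if seed is not None else None
    a = y.mean(axis=1)
    yd = y - a[:, None]

    params = _init_params(yd, e, init_cov_scale, obs_var_floor, rng)
    if init is not None:
        # warm start: keep the carried-over parameters only if they
        # explain the current window at least as well as the
        # data-driven init (a stale warm start can trap EM in a flat
        # region, e.g. right after a level shift)
        if init.Z.shape != (n, e):
            raise ValueError("warm-start params have incompatible shape")
        warm = SSMParams(
            Z=init.Z.copy(),
            a=np.zeros(n),
            Q=np.eye(e),
            R=np.diag(np.maximum(np.diag(init.R), obs_var_floor)),
            pi=np.zeros(e),
            Lambda=init_cov_scale * np.eye(e),
        )
        try:
            if kalman_filter(warm, yd).log_likelihood >= kalman_filter(params, yd).log_likelihood:
                params = warm
        except np.linalg.LinAlgError:
            pass

    if np.allclose(yd.var(axis=1), 0.0):
        # constant input: a already explains everything
        filt = kalman_filter(params, yd)
        return EMFit(replace(params, a=a), np.array([filt.log_likelihood]), True, 0)

    support = _constrained_row_support(n, e)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        filt = kalman_filter(params, yd)
        trace.append(filt.log_likelihood)
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if cur + 1e-9 * max(1.0, abs(prev)) < prev:
                # exact E/M steps are monotone; tiny decreases arise from
                # round-off on near-degenerate windows (R at its floor)
                log = logger.warning if prev - cur > 1e-6 * max(1.0, abs(prev)) else logger.debug
                log("EM log-likelihood decreased at iter %d (%g -> %g)", it, prev, cur)
            if abs(cur - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break
        sm = kalman_smooth(filt, params)
        xs = sm.smoothed_means
        S11 = sm.smoothed_covs.sum(axis=0) + xs @ xs.T  # sum_t E[x_t x_t']
        Sxy = xs @ yd.T  # (e, n): sum_t E[x_t] y_t'
        Z = np.zeros((n, e))
        for i in range(n):
            ji = support[i]
            Z[i, ji] = np.linalg.solve(
                S11[np.ix_(ji, ji)] + 1e-12 * np.eye(ji.size), Sxy[ji, i]
            )
        resid = (yd * yd).sum(axis=1) - 2.0 * np.einsum("ij,ji->i", Z, Sxy) + np.einsum(
            "ij,jk,ik->i", Z, S11, Z
        )
        Rdiag = np.maximum(resid / T, obs_var_floor)
        params = replace(params, Z=Z, R=np.diag(Rdiag))

    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (rel tol {tol})",
            RuntimeWarning,
            stacklevel=2,
        )
    return EMFit(replace(params, a=a), np.asarray(trace), converged, it)


class GaussianRandomWalkSSM(BaseEstimator):
    """scikit-learn estimator for the random-walk-trend state-space model.

    ``fit`` expects ``Y`` with shape ``(n_timepoints, n_variables)``
    (time along rows, as samples).  Fitted attributes expose the
    estimated parameters; ``score`` returns the exact log-likelihood.

    Parameters
    ----------
    n_trends : int, default 3
        Number of hidden random-walk trends ``e``.
    tol, max_iter : EM stopping rule (relative log-likelihood change).
    init_cov_scale : float, default 5.0
        Fixed diffuse initial state covariance ``Lambda = scale * I``.
    obs_var_floor : float, default 1e-8
        Lower bound on the diagonal of ``R``.
    """

    def __init__(
        self,
        n_trends: int = 3,
        tol: float = 1e-6,
        max_iter: int = 200,
        init_cov_scale: float = 5.0,
        obs_var_floor: float = 1e-8,
        random_state=None,
    ):
        self.n_trends = n_trends
        self.tol = tol
        self.max_iter = max_iter
        self.init_cov_scale = init_cov_scale
        self.obs_var_floor = obs_var_floor
        self.random_state = random_state

    def _validate(self, Y) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (n_timepoints, n_variables)")
        return Y.T  # internal convention: (n, T)

    def fit(self, Y, y=None, init: SSMParams | None = None):
        yv = self._validate(Y)
        fit = em_fit(
            yv,
            e=self.n_trends,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.random_state,
            init=init,
            init_cov_scale=self.init_cov_scale,
            obs_var_floor=self.obs_var_floor,
        )
        self.params_ = fit.params
        self.loadings_ = fit.params.Z
        self.offset_ = fit.params.a
        self.obs_variances_ = np.diag(fit.params.R)
        self.loglik_trace_ = fit.loglik_trace
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.n_features_in_ = yv.shape[0]
        return self

    def filter(self, Y) -> FilterResult:
        return kalman_filter(self.params_, self._validate(Y))

    def smooth(self, Y) -> FilterResult:
        filt = self.filter(Y)
        return kalman_smooth(filt, self.params_)

    def forecast(self, Y, lam: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Forecast ``lam`` steps past the end of ``Y``."""
        filt = self.filter(Y)
        return forecast(self.params_, filt, t=filt.y.shape[1] - 1, lam=lam)

    def score(self, Y, y=None) -> float:
        return self.filter(Y).log_likelihood

    def sample(self, T: int, seed=None) -> np.ndarray:
        _, yv = simulate(self.params_, T, seed=seed)
        return yv.T
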