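r"""Moving-window early-warning indicators.

Surprise loss (SL) quantifies forecast breakdown: with a state-space
model fitted on the window ``t-m+1..t`` (parameters ``theta_t``), the
out-of-sample quadratic loss of the :math:`\lambda`-step-ahead forecast
is compared with the average in-sample loss over the window::

    SL_{t+lambda} = L_{t+lambda}(theta_t) - (1/m) * sum_{j=t-m+1}^{t} L_j(theta_t)

where ``L_j = (1/n) sum_k (y(k)_j - yhat(k)_j)^2``.  A trailing moving
average of width ``delta`` (SLMean) removes short-term fluctuation, and
the index of the maximal SLMean (``t_max``) is taken as the putative
critical transition.  Classical early-warning baselines -- moving-window
lag-1 autocorrelation (AC1) and variance (VAR), averaged across
variables -- are provided for comparison.

Indexing convention: all arrays are 0-based and aligned with the input
series; the SL produced by the window ending at column ``t`` is stored
at column ``t + lambda`` (the time at which the surprise is realized).
Entries outside an indicator's validity range are NaN.
"""
from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .ssm import EMFit, SSMParams, em_fit, forecast as ssm_forecast, kalman_filter, kalman_smooth, _psd_sqrt

logger = logging.getLogger(__name__)


def patient_seed(master_seed: int | None, patient_id: str) -> int:
    """Stable per-patient seed: master seed combined with an id hash."""
    h = zlib.crc32(str(patient_id).encode("utf8"))
    return int((0 if master_seed is None else int(master_seed)) * 2654435761 + h) % (2**31)


def in_sample_loss(y_window: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Per-index quadratic losses L_j = (1/n) sum_k (y_kj - yhat_kj)^2."""
    y_window = np.atleast_2d(y_window)
    y_hat = np.atleast_2d(y_hat)
    if y_window.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y_window.shape} vs {y_hat.shape}")
    return ((y_window - y_hat) ** 2).mean(axis=0)


def out_of_sample_loss(y_future: np.ndarray, y_forecast: np.ndarray) -> float:
    """Quadratic loss of a single lambda-step-ahead forecast vector."""
    y_future = np.asarray(y_future, dtype=float).ravel()
    y_forecast = np.asarray(y_forecast, dtype=float).ravel()
    if y_future.shape != y_forecast.shape:
        raise ValueError(f"shape mismatch: {y_future.shape} vs {y_forecast.shape}")
    return float(((y_future - y_forecast) ** 2).mean())


@dataclass
class SLTrace:
    """Per-time-index surprise loss for one patient.

    ``sl[i]`` / ``slmean[i]`` are NaN outside their validity ranges.
    The per-window forecast moments and in-sample means are retained so
    prediction-interval uncertainty can be resampled afterwards.
    """

    patient_id: str
    sl: np.ndarray
    slmean: np.ndarray | None
    window: int  # m
    n_trends: int  # e
    horizon: int  # lambda
    smooth: int | None  # delta
    t_max: int | None = None
    t_max_up: int | None = None
    t_max_low: int | None = None
    onset_index: int | None = None
    bin_width: float = 0.5
    converged: np.ndarray | None = None  # per stored index
    forecast_mean: np.ndarray | None = None  # (n, T)
    forecast_cov: np.ndarray | None = None  # (T, n, n)
    insample_mean: np.ndarray | None = None  # (T,)
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.sl.size


@dataclass
class IndicatorTrace:
    """Moving-window baseline indicator (AC1 or VAR) for one patient."""

    patient_id: str
    kind: str  # "AC1" | "VAR"
    values: np.ndarray
    window: int
    t_max: int | None = None
    onset_index: int | None = None
    bin_width: float = 0.5


def surprise_loss_series(
    y: np.ndarray,
    m: int,
    e: int,
    lam: int = 1,
    seed=None,
    insample: str = "predicted",
    warm_start: bool = True,
    patient_id: str = "",
    onset_index: int | None = None,
    bin_width: float = 0.5,
    em_options: dict | None = None,
) -> SLTrace:
    """Compute the surprise-loss series over a complete (n, T) matrix.

    For every window end ``t`` (0-based, ``t = m-1 .. T-1-lam``) the
    constrained state-space model is fitted by EM on columns
    ``t-m+1..t`` and the surprise realized at ``t+lam`` is stored there.

    Parameters
    ----------
    insample : {"predicted", "smoothed"}
        How the in-sample estimates ``yhat_j`` are formed.
        ``"predicted"`` applies the forecast rule within the window
        (lambda-step predictions from filtered states, the window start
        predicting from the prior), so in- and out-of-sample losses are
        directly comparable and SL is centred near zero on stable
        dynamics.  ``"smoothed"`` uses the smoothed observation
        estimates ``Z x_{j|window} + a``.
    warm_start : bool
        Start each window's EM from the previous window's parameters
        (kept only when it explains the new window at least as well as
        a fresh data-driven init).
    em_options : dict, optional
        Overrides passed to the per-window EM.  Defaults to
        ``{"max_iter": 35}``: past a few tens of iterations the
        loadings only crawl along a weakly identified direction with a
        negligible (<1e-2) effect on the forecasts that enter SL.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, T = y.shape
    if T < m + lam:
        raise ValueError(f"need T >= m + lambda, got T={T}, m={m}, lambda={lam}")
    if insample not in ("predicted", "smoothed"):
        raise ValueError("insample must be 'predicted' or 'smoothed'")
    em_options = {"max_iter": 35, **(em_options or {})}

    sl = np.full(T, np.nan)
    conv = np.zeros(T, dtype=bool)
    fmean = np.full((n, T), np.nan)
    fcov = np.full((T, n, n), np.nan)
    imean = np.full(T, np.nan)

    prev_params: SSMParams | None = None
    for t in range(m - 1, T - lam):
        yw = y[:, t - m + 1 : t + 1]
        try:
            with warnings.catch_warnings():
                # hitting the window-fit iteration cap is expected; the
                # converged flags record it per index
                warnings.simplefilter("ignore", RuntimeWarning)
                fit: EMFit = em_fit(yw, e=e, seed=seed, init=prev_params, **em_options)
            params = fit.params
            filt = kalman_filter(params, yw)
            # out-of-sample: lambda-step forecast from the window end
            fc_mean, fc_cov = ssm_forecast(params, filt, t=m - 1, lam=lam)
            l_out = out_of_sample_loss(y[:, t + lam], fc_mean)
            # in-sample estimates over the window
            if insample == "smoothed":
                sm = kalman_smooth(filt, params)
                y_hat = params.Z @ sm.smoothed_means + params.a[:, None]
            else:
                y_hat = np.empty((n, m))
                prior = params.Z @ params.pi + params.a
                for j in range(m):
                    src = j - lam
                    if src < 0:
                        y_hat[:, j] = prior
                    else:
                        y_hat[:, j] = params.Z @ filt.filtered_means[:, src] + params.a
            l_in = in_sample_loss(yw, y_hat).mean()
            sl[t + lam] = l_out - l_in
            conv[t + lam] = fit.converged
            fmean[:, t + lam] = fc_mean
            fcov[t + lam] = fc_cov
            imean[t + lam] = l_in
            if warm_start:
                prev_params = params
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("window ending at %d failed (%s); SL left absent", t, err)
            prev_params = None
    return SLTrace(
        patient_id=patient_id,
        sl=sl,
        slmean=None,
        window=m,
        n_trends=e,
        horizon=lam,
        smooth=None,
        onset_index=onset_index,
        bin_width=bin_width,
        converged=conv,
        forecast_mean=fmean,
        forecast_cov=fcov,
        insample_mean=imean,
    )


def _trailing_mean(values: np.ndarray, delta: int) -> np.ndarray:
    """delta-width trailing mean over available (non-NaN) entries.

    Defined from the first index where the full delta-window lies inside
    the validity range of ``values``; windows with some absent entries
    average the available ones, all-absent windows stay NaN.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    T = values.size
    out = np.full(T, np.nan)
    finite = np.flatnonzero(np.isfinite(values))
    if finite.size == 0:
        return out
    start = finite[0] + delta - 1
    for t in range(start, T):
        w = values[t - delta + 1 : t + 1]
        w = w[np.isfinite(w)]
        if w.size:
            out[t] = w.mean()
    return out


def slmean(trace: SLTrace, delta: int) -> SLTrace:
    """Fill ``trace.slmean`` with the delta-width trailing mean of SL."""
    trace.slmean = _trailing_mean(trace.sl, delta)
    trace.smooth = delta
    return trace


def find_tmax(
    values_or_trace,
    onset_index: int | None = None,
    tie_tol: float = 1e-12,
) -> int:
    """Index of the global maximum of SLMean (or any indicator curve).

    Exact ties (within ``tie_tol``) resolve to the index closest to
    ``onset_index``; with no onset, the latest tied index is taken
    (the series end plays the role of onset/discharge).
    """
    if isinstance(values_or_trace, SLTrace):
        values = values_or_trace.slmean
        if onset_index is None:
            onset_index = values_or_trace.onset_index
    else:
        values = np.asarray(values_or_trace, dtype=float)
    if values is None or not np.any(np.isfinite(values)):
        raise ValueError("no defined indicator values to maximize")
    vmax = np.nanmax(values)
    ties = np.flatnonzero(np.isfinite(values) & (values >= vmax - tie_tol))
    if onset_index is None:
        return int(ties[-1])
    return int(ties[np.argmin(np.abs(ties - onset_index))])


def slmean_uncertainty(
    y: np.ndarray,
    trace: SLTrace,
    B: int = 1000,
    seed=None,
) -> tuple[int, int, tuple[float, float]]:
    """t_max of the 95% prediction-interval bounds of SLMean.

    For every valid index, ``B`` forecasts are drawn from the stored
    forecast distribution ``MVN(yhat_{t+lambda}, F_{t+lambda})``, SL is
    recomputed per draw, and the pointwise 2.5%/97.5% quantiles are
    smoothed with the same delta filter.  Returns the argmax indices of
    the upper/lower bound curves and their deviations from ``t_max`` in
    hours; sets ``trace.t_max_up`` / ``trace.t_max_low``.
    """
    if trace.slmean is None or trace.smooth is None:
        raise ValueError("compute slmean before the uncertainty bounds")
    if trace.forecast_mean is None:
        raise ValueError("trace lacks stored forecast moments")
    if B < 100:
        warnings.warn("B < 100 draws gives unstable quantiles", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, T = y.shape
    lo = np.full(T, np.nan)
    hi = np.full(T, np.nan)
    for i in np.flatnonzero(np.isfinite(trace.sl)):
        f = trace.forecast_mean[:, i]
        L = _psd_sqrt(trace.forecast_cov[i])
        draws = f[None, :] + rng.standard_normal((B, n)) @ L.T
        sl_draws = ((y[:, i][None, :] - draws) ** 2).mean(axis=1) - trace.insample_mean[i]
        lo[i], hi[i] = np.quantile(sl_draws, [0.025, 0.975])
    lo_s = _trailing_mean(lo, trace.smooth)
    hi_s = _trailing_mean(hi, trace.smooth)
    if trace.t_max is None:
        trace.t_max = find_tmax(trace)
    t_up = find_tmax(hi_s, onset_index=trace.onset_index)
    t_low = find_tmax(lo_s, onset_index=trace.onset_index)
    trace.t_max_up, trace.t_max_low = t_up, t_low
    dev = (
        (t_up - trace.t_max) * trace.bin_width,
        (t_low - trace.t_max) * trace.bin_width,
    )
    return t_up, t_low, dev


def _window_view(y: np.ndarray, m: int) -> np.ndarray:
    """(n, T-m+1, m) sliding windows along time."""
    return np.lib.stride_tricks.sliding_window_view(y, m, axis=1)


def ac1_series(
    y: np.ndarray,
    m: int,
    patient_id: str = "",
    onset_index: int | None = None,
    bin_width: float = 0.5,
) -> IndicatorTrace:
    """Moving-window lag-1 autocorrelation averaged over variables.

    Zero-variance windows contribute 0 to the average, keeping the
    divisor fixed at the number of variables.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, T = y.shape
    if not 3 <= m <= T:
        raise ValueError(f"need 3 <= m <= T, got m={m}, T={T}")
    w = _window_view(y, m)  # (n, T-m+1, m)
    c = w - w.mean(axis=2, keepdims=True)
    num = (c[:, :, :-1] * c[:, :, 1:]).sum(axis=2)
    den = (c**2).sum(axis=2)
    ac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    values = np.full(T, np.nan)
    values[m - 1 :] = ac.mean(axis=0)
    return IndicatorTrace(
        patient_id=patient_id,
        kind="AC1",
        values=values,
        window=m,
        t_max=find_tmax(values, onset_index=onset_index),
        onset_index=onset_index,
        bin_width=bin_width,
    )


def var_series(
    y: np.ndarray,
    m: int,
    patient_id: str = "",
    onset_index: int | None = None,
    bin_width: float = 0.5,
) -> IndicatorTrace:
    """Moving-window sample variance averaged over variables."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, T = y.shape
    if not 2 <= m <= T:
        raise ValueError(f"need 2 <= m <= T, got m={m}, T={T}")
    w = _window_view(y, m)
    values = np.full(T, np.nan)
    values[m - 1 :] = w.var(axis=2, ddof=1).mean(axis=0)
    return IndicatorTrace(
        patient_id=patient_id,
        kind="VAR",
        values=values,
        window=m,
        t_max=find_tmax(values, onset_index=onset_index),
        onset_index=onset_index,
        bin_width=bin_width,
    )


def robustness_scan(
    y: np.ndarray,
    m_values=(24, 30),
    e_values=(4, 5),
    reference: tuple[int, int] = (36, 3),
    lam: int = 1,
    delta: int = 6,
    seed=None,
    onset_index: int | None = None,
    bin_width: float = 0.5,
    **sl_kwargs,
):
    """t_max shift under perturbed window length / trend count.

    Recomputes the SLMean trace for the reference setting and for every
    ``(m, e)`` combination drawn from ``m_values x {e_ref}`` and
    ``{m_ref} x e_values``, and reports ``t_max(setting) -
    t_max(reference)`` in bins and hours.  Failed settings appear with
    NaN deltas.  Returns a pandas DataFrame.
    """
    import pandas as pd

    m_ref, e_ref = reference

    def _tmax(m, e):
        tr = surprise_loss_series(
            y, m=m, e=e, lam=lam, seed=seed, onset_index=onset_index,
            bin_width=bin_width, **sl_kwargs,
        )
        slmean(tr, delta)
        return find_tmax(tr)

    t_ref = _tmax(m_ref, e_ref)
    rows = [dict(m=m_ref, e=e_ref, t_max=t_ref, delta_bins=0, delta_h=0.0, reference=True)]
    settings = [(m, e_ref) for m in m_values] + [(m_ref, e) for e in e_values]
    for m, e in settings:
        try:
            t = _tmax(m, e)
            rows.append(dict(m=m, e=e, t_max=t, delta_bins=t - t_ref,
                             delta_h=(t - t_ref) * bin_width, reference=False))
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("robustness setting (m=%d, e=%d) failed: %s", m, e, err)
            rows.append(dict(m=m, e=e, t_max=np.nan, delta_bins=np.nan,
                             delta_h=np.nan, reference=False))
    return pd.DataFrame(rows)


class _MovingWindowIndicator(BaseEstimator):
    """Shared fit plumbing; Y is (n_timepoints, n_variables)."""

    def _series(self, Y) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.ndim != 2:
            raise ValueError("Y must be 1-D or 2-D (time along axis 0)")
        return Y.T


class SurpriseLossIndicator(_MovingWindowIndicator):
    """Surprise-loss early-warning indicator as a scikit-learn estimator.

    ``fit(Y)`` computes the SL series, its SLMean smoothing, and the
    critical-transition index on a complete multivariate series with
    time along rows.  Defaults follow the reference analysis settings
    (window m = 36 bins = 18 h, e = 3 trends, one-step-ahead forecast,
    delta = 6 bins = 3 h smoothing at 30-minute bins).

    Attributes
    ----------
    sl_, slmean_ : per-index indicator values (NaN outside validity)
    t_max_ : int, critical-transition index
    trace_ : the underlying :class:`SLTrace`
    """

    def __init__(
        self,
        window: int = 36,
        n_trends: int = 3,
        horizon: int = 1,
        smooth: int = 6,
        insample: str = "predicted",
        warm_start: bool = True,
        bin_width: float = 0.5,
        random_state=None,
    ):
        self.window = window
        self.n_trends = n_trends
        self.horizon = horizon
        self.smooth = smooth
        self.insample = insample
        self.warm_start = warm_start
        self.bin_width = bin_width
        self.random_state = random_state

    def fit(self, Y, y=None, onset_index: int | None = None, patient_id: str = ""):
        yv = self._series(Y)
        trace = surprise_loss_series(
            yv,
            m=self.window,
            e=self.n_trends,
            lam=self.horizon,
            seed=self.random_state,
            insample=self.insample,
            warm_start=self.warm_start,
            patient_id=patient_id,
            onset_index=onset_index,
            bin_width=self.bin_width,
        )
        slmean(trace, self.smooth)
        trace.t_max = find_tmax(trace)
        self.trace_ = trace
        self.sl_ = trace.sl
        self.slmean_ = trace.slmean
        self.t_max_ = trace.t_max
        self.n_features_in_ = yv.shape[0]
        return self

    def uncertainty(self, Y, B: int = 1000, seed=None):
        """95% prediction-interval argmax bounds for the fitted trace."""
        return slmean_uncertainty(self._series(Y), self.trace_, B=B, seed=seed)


class AutocorrelationIndicator(_MovingWindowIndicator):
    """Moving-window lag-1 autocorrelation baseline (AC1)."""

    def __init__(self, window: int = 36, bin_width: float = 0.5):
        self.window = window
        self.bin_width = bin_width

    def fit(self, Y, y=None, onset_index: int | None = None, patient_id: str = ""):
        trace = ac1_series(self._series(Y), self.window, patient_id=patient_id,
                           onset_index=onset_index, bin_width=self.bin_width)
        self.trace_ = trace
        self.values_ = trace.values
        self.t_max_ = trace.t_max
        return self


class VarianceIndicator(_MovingWindowIndicator):
    """Moving-window variance baseline (VAR)."""

    def __init__(self, window: int = 36, bin_width: float = 0.5):
        self.window = window
        self.bin_width = bin_width

    def fit(self, Y, y=None, onset_index: int | None = None, patient_id: str = ""):
        trace = var_series(self._series(Y), self.window, patient_id=patient_id,
                           onset_index=onset_index, bin_width=self.bin_width)
        self.trace_ = trace
        self.values_ = trace.values
        self.t_max_ = trace.t_max
        return self
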