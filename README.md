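# slwarn

Early-warning analysis of multivariate clinical time series based on
**surprise loss**: detect critical transitions — abrupt shifts between
dynamical regimes, such as the deterioration preceding septic shock —
by monitoring when a model's forecasts break down relative to its own
past performance.

The package is aimed at researchers working with ICU chart/lab
extracts (irregular, sparse, heterogeneous long-format event tables)
who want an unsupervised, per-patient transition indicator and a
cohort-level way to exploit it.

## Method

Each patient's series is binned to 30-minute intervals, gap-filled
with Stineman interpolation, Z-scored, and modelled over a moving
window of width *m* by a linear-Gaussian state-space model with *e*
random-walk hidden trends:

    x_t = x_{t-1} + w_t,   w_t ~ N(0, Q)
    y_t = Z x_t + a + v_t, v_t ~ N(0, R)

fitted by constrained EM (Kalman filter/smoother E-step; Q = I, upper
triangle of the first *e* rows of Z fixed at 0, R diagonal).  With
window-fitted parameters θ̂_t, the **surprise loss** at horizon λ is
the out-of-sample quadratic loss minus the average in-sample loss,

    SL_{t+λ} = L_{t+λ}(θ̂_t) − (1/m) Σ_{j=t−m+1}^{t} L_j(θ̂_t),
    L_j = (1/n) Σ_k (y(k)_j − ŷ(k)_j)²,

smoothed by a trailing δ-width moving average (**SLMean**).  The index
of maximal SLMean, *t_max*, marks the putative critical transition;
resampling the forecast distribution gives 95% prediction-interval
bounds on its location.  Classical early-warning baselines —
moving-window lag-1 autocorrelation (AC1) and variance (VAR) — are
computed on the same windows for comparison.

At the cohort level, observables sampled at each patient's *t_max*
are compared between conditions per variable (Wilcoxon rank-sum +
Benjamini–Hochberg), and a bootstrap quantifies the advantage over
random sampling: **BF**, the fraction of replications in which the
*t_max* p-value beats the p-value at random time indices (over the
full stay, or the last 36 h/18 h before onset).

Default settings: m = 36 bins (18 h), e = 3, λ = 1 bin (30 min),
δ = 6 bins (3 h).  See `docs/methods.md` for assumptions, numerical
choices and limitations.

## Worked example

The canonical benchmark: a univariate series of three 50-point
stationary segments (means 5, 10, 15, sd 0.5) has regime changes at
indices 50 and 100.

```python
import numpy as np
from scipy.signal import find_peaks
from slwarn import make_segmented_series, surprise_loss_series

series = make_segmented_series(seed=0)           # ground truth: [50, 100]
trace = surprise_loss_series(series.values, m=30, e=1, lam=1, seed=0)

sl = np.where(np.isfinite(trace.sl), trace.sl, -np.inf)
peaks, _ = find_peaks(sl)
top2 = np.sort(peaks[np.argsort(sl[peaks])[-2:]]) + 1     # 1-based
print("change points:", series.meta["change_points"])
print("dominant SL peaks:", [int(i) for i in top2])
print("SL at peaks:", np.round(sl[top2 - 1], 1))
print("median |SL| elsewhere:", round(float(np.nanmedian(np.abs(trace.sl))), 2))
```

prints

```
change points: [50, 100]
dominant SL peaks: [51, 101]
SL at peaks: [24.9 26.9]
median |SL| elsewhere: 0.41
```

The surprise loss spikes one forecast step (λ = 1) after each true
boundary — SL ≈ 25 against a background with median magnitude 0.4 —
because the model fitted on the pre-boundary window mispredicts the
first point of the new regime by ~5 units (10 within-segment sd).

The same machinery runs from the shell on long-format CSVs:

```sh
slwarn simulate --kind icu --seed 0 --out data/
slwarn indicator --events data/events.csv --labels data/labels.csv --out traces/
slwarn cohort --events data/events.csv --labels data/labels.csv --out stats/
slwarn robustness --events data/events.csv --labels data/labels.csv --out robust/
```

`indicator` writes per-patient SL/SLMean/AC1/VAR traces and a *t_max*
summary; `cohort` writes per-variable p-values, BH-adjusted p-values
and BF for the full/36 h/18 h sampling modes; `robustness` reports how
*t_max* moves when (m, e) are perturbed.

Note: the study this package operationalizes analyzed a credentialed
clinical database (630 septic-shock and 6,236 non-sepsis admissions);
its cohort-level numbers (e.g. median early-warning lead time of
35.6 h) require that data and are not reproduced here.  Everything in
this repository runs on synthetic data with known ground truth.

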