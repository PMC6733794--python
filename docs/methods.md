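# Methods

## The model

Each patient's preprocessed multivariate series `y_t` (n variables,
30-minute bins) is described, locally in time, by a linear-Gaussian
state-space model with random-walk hidden trends:

    x_t = x_{t-1} + w_t,      w_t ~ MVN(0, Q),  x_0 ~ MVN(pi, Lambda)
    y_t = Z x_t + a + v_t,    v_t ~ MVN(0, R)

The `e` hidden trends (`e << n`) stand in for unobserved physiological
processes; the observables are noisy linear combinations of them, so
the model separates process variability (`Q`) from measurement noise
(`R`).  The model is deliberately simple — the indicator below is
designed to be robust to this kind of misspecification because it
compares the model's forecasting ability against its own past
performance rather than against an absolute standard.

### Identifiability and estimation

A factor model of this form is only identified up to rotations and
scalings of the hidden trends.  We adopt the standard dynamic-factor
constraint set: `Q = I_e` fixed (the trend scale lives in `Z`),
`Z[i, j] = 0` for `j > i` in the first `e` rows, `R` diagonal with
unequal variances, `pi = 0` and `Lambda = 5 I_e` fixed (diffuse on
Z-scored data).  The offset `a` is profiled out by demeaning each
fitting window and storing the mean; under these constraints that is
equivalent to estimating it and considerably cheaper and stabler.  It
also matters substantively: with `Q` fixed, a moving offset lets the
loadings stay small on locally stationary stretches instead of forcing
the random walk to carry the level.

Estimation is EM with an exact E-step (Kalman filter + RTS smoother;
innovation covariances are Cholesky-factorized with a jitter retry of
1e-10 growing tenfold up to three times) and an exact M-step: with `R`
diagonal the constrained update of each row of `Z` is an ordinary
least-squares solve on that row's free loadings, followed by the exact
`R` update given the new `Z`, so the log-likelihood is non-decreasing
by construction (asserted in tests to 1e-9 relative slack).  `R`'s
diagonal is floored at 1e-8; a window-constant variable keeps its row
with a floored variance rather than being dropped, so `n` is stable
across windows.

Two numerical choices matter in practice and were found by
experiment:

* **Initialization** uses an SVD of the *differenced* series.  Under a
  random-walk trend the levels grow like sqrt(T), so a levels-SVD
  overestimates the loading scale by an order of magnitude and EM then
  crawls for hundreds of iterations toward the right scale.  The
  increments identify the scale directly (`Var(dy) = Z Z' + 2R`).
* **Warm starts with a guard.**  Moving-window fits start from the
  previous window's parameters, but only if those parameters explain
  the new window at least as well (one filter evaluation) as the fresh
  data-driven init.  An unguarded warm start is actively harmful right
  after a level shift: the stale parameters (near-zero loadings fitted
  to a stationary stretch) are a local trap, the filter gain stays
  near zero, and the surprise-loss response smears into a broad
  plateau instead of a sharp peak.

`em_fit` defaults to `tol = 1e-6` (relative log-likelihood) and
`max_iter = 200`.  Inside the moving-window loop the cap is 35: past a
few tens of iterations the loadings only crawl along a weakly
identified direction; against a 200-iteration / 1e-8 reference fit the
forecasts change by < 1e-2 and the SL series by < 0.08 (SL sd ~0.24 on
the same data).

## Surprise loss

With a window of width `m` ending at `t` and window-fitted parameters
`theta_t`, the quadratic losses are

    L_j        = (1/n) sum_k (y(k)_j - yhat(k)_j)^2          (in-sample)
    L_{t+lam}  = (1/n) sum_k (y(k)_{t+lam} - ytilde(k))^2    (out-of-sample)

where `ytilde = Z x_{t|t} + a` is the lambda-step-ahead forecast
(under the random-walk transition the forecast mean is independent of
lambda; its covariance is `F = Z (P_{t|t} + lam Q) Z' + R`), and

    SL_{t+lam} = L_{t+lam} - (1/m) sum_{j=t-m+1}^{t} L_j .

SL is stored at index `t + lam`, the time at which the surprise is
realized.  SLMean is the plain delta-width trailing mean of SL,
defined from the first index with a full smoothing window; the printed
form of the smoother in the source material (divisor `j`, summation
width `m + delta`) is inconsistent with its own description as "a
moving-average filter with size delta" and is implemented as the
latter.  The critical-transition index `t_max` is the argmax of
SLMean; exact ties resolve toward the clinical onset when one is
known, otherwise to the latest index (the series end plays the role of
onset/discharge).

**In-sample estimates.**  `yhat_j` defaults to the forecast rule
applied within the window: the lambda-step prediction from the
filtered state at `j - lam` (the prior mean for the first lambda
indices).  This matches the construction in the econometric
forecast-breakdown literature the indicator comes from, and it makes
the in- and out-of-sample losses directly comparable, so SL is centred
near zero on change-free data.  The alternative reading — smoothed
observation estimates `Z x_{j|window} + a` — is available via
`insample="smoothed"`, but note that smoothed fits are systematically
closer to the data than any forecast can be, which gives SL a positive
mean even on perfectly stable series.

Even with the default, SL retains a small positive bias of order
`2 sigma^2 / m` on stationary data: the window mean (the profiled
offset) is estimated on the window and evaluated outside it.  At
`m = 36` this is ~0.06 in Z-scored units, below the per-series
2-standard-error resolution of the null-calibration check but visible
in principle at very large pooled sample sizes.  This is intrinsic to
surprise loss with window-estimated parameters; the indicator is used
for localization (argmax), not as a calibrated test statistic, and the
source material explicitly declines to test SL's mean.

**Uncertainty.**  For each index, `B = 1000` forecasts are drawn from
`MVN(ytilde, F)`, SL is recomputed per draw, the pointwise 2.5%/97.5%
quantiles are smoothed with the same delta filter, and the argmaxes of
the two bound curves give `t_max(up)`/`t_max(low)`.  Their deviations
from `t_max` (in hours) measure how firmly the transition is located.

**Baselines.**  AC1 and VAR are the moving-window lag-1
autocorrelation and sample variance, computed per variable over the
same windows and averaged across variables; a zero-variance window
contributes 0 to the AC1 average so the divisor stays fixed.

## Cohort statistics

Observables are sampled at each patient's `t_max` (blind to the
condition label), assembled into per-condition matrices, and compared
per variable with the two-sided Wilcoxon rank-sum test (exact null
distribution when the smaller cohort has at most 8 patients and the
pooled row is tie-free; midranks + normal approximation with
continuity correction otherwise), followed by Benjamini-Hochberg
adjustment.  The bootstrap frequency (BF) of a variable is the
fraction of replications (default 1000) in which the t_max p-value is
strictly smaller than the p-value at per-patient random time indices:
uniform over the stay ("full" mode) or over the last 36 h / 18 h
before onset (before end of stay for patients without an onset;
windows are clamped to short stays).  One random index is drawn per
patient per replication.  Ties count against the t_max sampling, as
printed in the source definition.  A consequence worth knowing: with
small cohorts the rank-sum p-value is coarsely discrete and the tie
probability alone depresses the null BF to ~0.43-0.45 rather than 0.5
(at hundreds of patients per arm ties are negligible and the null BF
sits at 0.5).

## Preprocessing

Events are averaged into half-open 30-minute bins anchored at
admission; the shock index (HR/SBP) and BUN/creatinine ratio are
derived per bin where both inputs are observed (zero denominators stay
missing); interior gaps are filled by Stineman's rational
interpolation (circle-tangent slopes; deviation from the secant in
each interval bounded by the smaller endpoint-tangent deviation, which
is what suppresses overshoot on sharp changes) and leading/trailing
gaps by nearest-observed-value extension; each variable is then
Z-scored per patient over that patient's own bins (zero-variance
variables map to 0).  Per-patient normalization avoids any cohort-level
leakage into an indicator that is meant to be computable online for a
single patient; the cohort-pooled alternative was rejected for that
reason.

Suspicion of infection is annotated from treatment timelines:
antibiotics within 72 h after any prior body-fluid sampling, or fluid
sampling within 24 h after any prior antibiotic (closed intervals;
equal timestamps count as prior).  Around each suspected timestamp the
window `[IST - 48 h, IST + 24 h]` is evaluated by a caller-supplied
predicate (a full organ-dysfunction score is out of scope; the
predicate interface lets tests and users plug one in), and the first
satisfied window yields onset `max(IST - 48, 0)`.  Septic series are
truncated at the onset bin, so the series end coincides with onset, as
discharge/death does for controls.

## Synthetic data: what it emulates and what it does not

* `make_segmented_series` — piecewise-stationary i.i.d. normal
  segments (default 3 x 50 points, means 5/10/15, sd 0.5).  The
  canonical change-point benchmark: with `m = 30`, `e = 1`,
  `lambda = 1`, the two dominant SL peaks land within 1-2 bins after
  the boundaries at 50 and 100.
* `make_ssm_cohort` — exact draws from the state-space model, used for
  parameter recovery and null calibration (`Z = 0` gives stationary
  white-noise observations, the natural change-free control).
* `make_icu_cohort` — irregular event tables with per-variable daily
  sampling rates in the range reported for septic-shock chart data
  (vitals ~20/day, labs ~1.5-2.5/day), stays of 36-144 h before onset.
  Values are a stationary mean-reverting (Ornstein-Uhlenbeck)
  physiological signal (sd 1, correlation time 12 h, sampled exactly
  at the event times) plus iid measurement noise (sd 0.25).  The
  autocorrelation matters: if consecutive measurements of a variable
  were independent draws — early versions of this generator did that —
  then post-imputation Z-scoring (whose sd is shrunk by the smooth
  interpolated stretches) amplifies every observed point of a sparse
  variable into a ~4-z "surprise", and these artifacts out-compete any
  genuine transition.  Real labs and vitals are strongly correlated
  between consecutive measurements.  Labs are drawn as shared specimen
  panels
  (chemistry, CBC) so related analytes are co-observed — necessary for
  the BUN/creatinine marker and true of real charts — and every
  variable has an admission-time record, because a variable that
  "switches on" mid-stay after a long nearest-value edge fill
  generates a spurious forecast-breakdown peak.  Septic patients get a
  mean shift (default 4 marginal-sd on 5 of 17 variables) from 12 h
  before onset, and a treatment timeline built so the annotation rules
  recover the intended onset exactly.

  The default cohort size (15 per condition) is a power choice: after
  Z-scoring, the programmed shift separates the sampled values by
  ~1.5-2 z-units, and a rank test at a multiplicity-corrected 5% level
  over ~19 variables needs roughly 15 patients per group to detect
  that reliably.

  What the generator does **not** emulate: cross-variable correlation
  of the baselines, unit scales and clinically plausible absolute
  values (everything is in noise-sd units; the pipeline Z-scores
  anyway), treatment-driven dynamics, gradual (non-step) deterioration,
  and informative sampling (sicker patients being measured more
  often).  Passing the end-to-end checks therefore demonstrates that
  the machinery detects localized distributional change under
  realistic sampling sparsity — not that it detects sepsis in real
  charts.

## Degenerate inputs and tie-breaks

Empty event tables and non-finite records are rejected with the
offending index; a variable with no observation in a stay fails
imputation with its name (the generator always emits at least one
record per variable); a derived marker with no jointly observed bin is
skipped with a warning; constant windows get floored observation
variances; all-NaN SLMean raises on `t_max`; `t_max` ties break toward
onset / latest as above; bootstrap windows longer than a stay are
clamped with a warning.

## Reference settings

`m = 36` bins (18 h), `e = 3`, `lambda = 1` bin (30 min), `delta = 6`
bins (3 h), bin width 0.5 h, `B = 1000` interval draws, 1000 bootstrap
replications (200 in the desk-scale end-to-end checks), robustness
grid `m in {24, 30}`, `e in {4, 5}` against reference `(36, 3)`.
Per-patient seeds derive from a master seed and a CRC32 hash of the
patient id.

## Known limitations

The SL localization degrades when competing genuine dynamics (drift,
monitoring artifacts) produce surprise peaks of the same magnitude as
the transition of interest; near-tied SLMean peaks make `t_max` flip
between runs that differ only in numerical detail.  The EM cap trades
a provably converged optimum for speed (measured effect on SL is
negligible, but the `converged` flags are recorded per window).  The
filter assumes complete data, so everything downstream inherits
whatever bias Stineman imputation introduces at very sparse variables.
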