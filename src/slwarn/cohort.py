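"""Critical-transition data sampling and cohort-level testing.

Observables are sampled at each patient's critical-transition index
(``t_max``), assembled into per-condition matrices ``S^c`` (variables x
patients), and compared per variable between the two cohorts with the
two-sided Wilcoxon rank-sum test plus Benjamini-Hochberg correction.
A bootstrap comparison quantifies the advantage over random sampling:
the bootstrap frequency (BF) of a variable is the fraction of
replications in which the t_max p-value beats the p-value obtained at
per-patient random time indices (drawn from the full stay, or from the
last 36 h / 18 h before onset).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BinnedSeries

logger = logging.getLogger(__name__)

#: random-sampling window widths (hours before onset/end of stay)
MODE_WIDTH_H = {"full": None, "36h": 36.0, "18h": 18.0}


@dataclass
class CohortSampleMatrix:
    """n-variable x v-patient matrix of observables sampled at t_max."""

    condition: str
    variables: list[str]
    matrix: np.ndarray  # (n, v)
    patient_ids: list[str]
    t_max: list[int]

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BootstrapResult:
    """Per-variable test results and bootstrap frequencies."""

    variables: list[str]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    bf: dict[str, np.ndarray] = field(default_factory=dict)
    reps: int = 0
    seed: int | None = None
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {"variable": self.variables, "p_raw": self.p_raw, "p_bh": self.p_adjusted}
        for mode, vals in self.bf.items():
            data[f"BF_{mode}"] = vals
        df = pd.DataFrame(data)
        df["reps"] = self.reps
        df["seed"] = self.seed
        return df


def _tmax_of(trace) -> int | None:
    t = getattr(trace, "t_max", None)
    return None if t is None else int(t)


def sample_at_tmax(
    cohort: list[tuple[BinnedSeries, object]],
) -> dict[str, CohortSampleMatrix]:
    """Gather each patient's observable column at its t_max, per condition.

    The sampling itself is blind to the condition label; labels are only
    used afterwards to split the columns into the per-condition
    matrices.  Patients without a valid ``t_max`` are excluded with a
    warning (the count is logged).
    """
    variables = None
    buckets: dict[str, list] = {}
    excluded = 0
    for series, trace in cohort:
        if variables is None:
            variables = list(series.variables)
        elif list(series.variables) != variables:
            raise ValueError("all patients must share the same variable set/order")
        t = _tmax_of(trace)
        if t is None or not 0 <= t < series.n_bins:
            excluded += 1
            continue
        label = series.condition_label or "unlabelled"
        buckets.setdefault(label, []).append((series.patient_id, t, series.values[:, t]))
    if excluded:
        warnings.warn(f"{excluded} patient(s) excluded (no valid t_max)", RuntimeWarning,
                      stacklevel=2)
    out = {}
    for label, cols in buckets.items():
        out[label] = CohortSampleMatrix(
            condition=label,
            variables=variables,
            matrix=np.column_stack([c[2] for c in cols]),
            patient_ids=[c[0] for c in cols],
            t_max=[c[1] for c in cols],
        )
    return out


def wilcoxon_pvalues(S0: np.ndarray, S1: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per variable (matrix row).

    Uses the exact null distribution when the smaller sample has at
    most 8 values and the pooled row is tie-free, otherwise the normal
    approximation with midranks and continuity correction.  Rows with
    an empty cohort yield NaN with a warning.
    """
    S0 = np.atleast_2d(S0)
    S1 = np.atleast_2d(S1)
    if S0.shape[0] != S1.shape[0]:
        raise ValueError("cohort matrices must have the same number of variables")
    p = np.full(S0.shape[0], np.nan)
    for i in range(S0.shape[0]):
        a, b = S0[i], S1[i]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            warnings.warn(f"variable row {i} empty in one cohort; p-value absent",
                          RuntimeWarning, stacklevel=2)
            continue
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (no_ties and min(a.size, b.size) <= 8) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        p[i] = res.pvalue
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _split_by_condition(cohort):
    labels = sorted({s.condition_label or "unlabelled" for s, _ in cohort})
    if len(labels) != 2:
        raise ValueError(f"need exactly two condition labels, got {labels}")
    return labels


def _random_index(series: BinnedSeries, mode: str, rng) -> int:
    """Uniform random bin in the mode's sampling window.

    ``full`` draws over the whole (onset-truncated) stay; ``36h``/``18h``
    draw from the corresponding interval before onset (or before the
    end of stay for patients without an onset), clamped to the stay.
    """
    end = series.n_bins
    if series.onset_index is not None:
        end = min(end, series.onset_index + 1)
    width_h = MODE_WIDTH_H[mode]
    if width_h is None:
        start = 0
    else:
        width_bins = int(round(width_h / series.bin_width))
        if width_bins > end:
            warnings.warn(
                f"{mode} window longer than patient {series.patient_id}'s stay; clamped",
                RuntimeWarning, stacklevel=2)
        start = max(0, end - width_bins)
    return int(rng.integers(start, end))


def bootstrap_frequency(
    cohort: list[tuple[BinnedSeries, object]],
    mode: str = "full",
    reps: int = 1000,
    seed=None,
    p_tmax: np.ndarray | None = None,
) -> np.ndarray:
    """Bootstrap frequency per variable for one sampling mode.

    Each replication draws one random time index per patient, rebuilds
    the cohort matrices at those columns, recomputes the per-variable
    rank-sum p-values, and counts (strictly) ``p_tmax < p_random``;
    ties count against the t_max sampling.
    """
    if mode not in MODE_WIDTH_H:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    labels = _split_by_condition(cohort)
    if p_tmax is None:
        mats = sample_at_tmax(cohort)
        p_tmax = wilcoxon_pvalues(mats[labels[0]].matrix, mats[labels[1]].matrix)
    usable = [(s, tr) for s, tr in cohort if _tmax_of(tr) is not None]
    nvar = usable[0][0].n_variables
    wins = np.zeros(nvar)
    valid = np.zeros(nvar)
    for _ in range(reps):
        cols = {lab: [] for lab in labels}
        for series, _tr in usable:
            t = _random_index(series, mode, rng)
            cols[series.condition_label or "unlabelled"].append(series.values[:, t])
        p_rand = wilcoxon_pvalues(
            np.column_stack(cols[labels[0]]), np.column_stack(cols[labels[1]])
        )
        ok = np.isfinite(p_tmax) & np.isfinite(p_rand)
        wins[ok] += (p_tmax[ok] < p_rand[ok]).astype(float)
        valid += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(valid > 0, wins / valid, np.nan)


def bootstrap_report(
    cohort: list[tuple[BinnedSeries, object]],
    modes=("full", "36h", "18h"),
    reps: int = 1000,
    seed=None,
) -> BootstrapResult:
    """Full per-variable report: raw/BH p-values and BF for each mode."""
    labels = _split_by_condition(cohort)
    mats = sample_at_tmax(cohort)
    for lab in labels:
        if lab not in mats:
            raise ValueError(f"cohort {lab!r} has no patient with a valid t_max")
    n_excluded = len(cohort) - sum(m.n_patients for m in mats.values())
    p_raw = wilcoxon_pvalues(mats[labels[0]].matrix, mats[labels[1]].matrix)
    ss = np.random.SeedSequence(seed)
    bf = {}
    for mode, child in zip(modes, ss.spawn(len(modes))):
        bf[mode] = bootstrap_frequency(
            cohort, mode=mode, reps=reps,
            seed=int(child.generate_state(1)[0] % (2**31)), p_tmax=p_raw,
        )
    return BootstrapResult(
        variables=list(mats[labels[0]].variables),
        p_raw=p_raw,
        p_adjusted=bh_adjust(p_raw),
        bf=bf,
        reps=reps,
        seed=seed,
        n_excluded=n_excluded,
    )


def label_permutation_bf(
    cohort: list[tuple[BinnedSeries, object]],
    n_permutations: int = 20,
    mode: str = "full",
    reps: int = 200,
    seed=None,
) -> np.ndarray:
    """BF values under random permutation of the condition labels.

    Null-calibration helper: with exchangeable cohorts the returned
    (n_permutations, n_variables) BF values centre near 0.5 (slightly
    below, since tied p-values count against t_max sampling).
    """
    rng = np.random.default_rng(seed)
    labels = [s.condition_label for s, _ in cohort]
    out = []
    for k in range(n_permutations):
        perm = rng.permutation(len(labels))
        shuffled = []
        for (series, trace), j in zip(cohort, perm):
            s2 = series.copy()
            s2.condition_label = labels[j]
            shuffled.append((s2, trace))
        out.append(
            bootstrap_frequency(shuffled, mode=mode, reps=reps,
                                seed=int(rng.integers(2**31)))
        )
    return np.asarray(out)
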