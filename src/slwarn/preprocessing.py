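"""Irregular clinical events -> regular, imputed, normalized series.

Implements the preprocessing chain applied to each ICU stay before any
indicator is computed: 30-minute time binning with within-bin averaging,
Stineman imputation of interior gaps (nearest-value extension at the
edges), derived septic markers (shock index, BUN/creatinine ratio),
per-patient Z-score normalization, and the retrospective annotation of
suspected-infection and onset times from treatment timelines.
"""
from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Sequence

import numpy as np

from ._stineman import stineman_interpolate
from .containers import BinnedSeries, RawEventTable, TreatmentTimeline

logger = logging.getLogger(__name__)

#: antibiotics within this many hours after a body-fluid sample imply
#: suspected infection (closed interval)
ANTIBIOTIC_AFTER_FLUID_H = 72.0
#: fluid sampling within this many hours after an antibiotic implies
#: suspected infection (closed interval)
FLUID_AFTER_ANTIBIOTIC_H = 24.0
#: onset window around an infection-suspected timestamp
ONSET_WINDOW_BEFORE_H = 48.0
ONSET_WINDOW_AFTER_H = 24.0

DEFAULT_MARKERS = (
    ("shock_index", "heart_rate", "systolic_bp"),
    ("bun_creatinine", "bun", "creatinine"),
)


def bin_series(events: RawEventTable, bin_width: float = 0.5) -> BinnedSeries:
    """Average raw records into half-open time bins of ``bin_width`` hours.

    Each cell holds the arithmetic mean of the raw values whose
    timestamps fall in that bin; cells without any record are NaN with
    ``observed_mask`` False.  Bins are anchored at admission (t0 = 0).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    df = events.records
    if len(df) == 0:
        raise ValueError(f"no data: patient {events.patient_id!r} has an empty event table")
    times = df["time_h"].to_numpy(dtype=float)
    vals = df["value"].to_numpy(dtype=float)
    bad = ~(np.isfinite(times) & np.isfinite(vals)) | (times < 0)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-finite or negative entry at record index {i} "
            f"(variable={df['variable'].iloc[i]!r}, time={times[i]}, value={vals[i]})"
        )
    variables = sorted(df["variable"].unique())
    var_index = {v: i for i, v in enumerate(variables)}
    bins = np.floor(times / bin_width).astype(int)
    n, T = len(variables), int(bins.max()) + 1
    total = np.zeros((n, T))
    count = np.zeros((n, T))
    rows = df["variable"].map(var_index).to_numpy()
    np.add.at(total, (rows, bins), vals)
    np.add.at(count, (rows, bins), 1.0)
    mask = count > 0
    values = np.full((n, T), np.nan)
    values[mask] = total[mask] / count[mask]
    onset_index = None
    if events.onset_time is not None:
        onset_index = min(int(math.floor(events.onset_time / bin_width)), T - 1)
    return BinnedSeries(
        patient_id=events.patient_id,
        variables=variables,
        values=values,
        observed_mask=mask,
        bin_width=bin_width,
        t0=0.0,
        onset_index=onset_index,
        condition_label=events.condition_label,
        meta=dict(events.meta),
    )


def impute_stineman(series: BinnedSeries) -> BinnedSeries:
    """Fill missing bins: Stineman interpolation between observed bins,
    nearest-observed-value extension before the first / after the last.

    Observed cells are never altered; the operation is idempotent.
    """
    out = series.copy()
    for i, name in enumerate(series.variables):
        obs = np.flatnonzero(series.observed_mask[i])
        if obs.size == 0:
            raise ValueError(f"variable {name!r} has zero observed bins; cannot impute")
        row = out.values[i]
        missing = np.flatnonzero(~series.observed_mask[i])
        if missing.size == 0:
            continue
        interior = missing[(missing > obs[0]) & (missing < obs[-1])]
        if interior.size:
            row[interior] = stineman_interpolate(obs.astype(float), row[obs], interior.astype(float))
        row[: obs[0]] = row[obs[0]]
        row[obs[-1] + 1 :] = row[obs[-1]]
    return out


def zscore_normalize(series: BinnedSeries) -> BinnedSeries:
    """Per-patient, per-variable Z-score over the patient's own bins.

    Variables with zero sample standard deviation map to all zeros.
    """
    out = series.copy()
    vals = out.values
    mean = np.nanmean(vals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, np.inf)  # sd=0 -> output 0
    out.values = (vals - mean) / sd
    return out


def derive_marker_variables(
    series: BinnedSeries,
    markers: Iterable[tuple[str, str, str]] = DEFAULT_MARKERS,
    require: bool = False,
) -> BinnedSeries:
    """Append derived marker variables (ratios of existing variables).

    Each marker is ``(name, numerator, denominator)``; by default the
    shock index (heart rate / systolic blood pressure) and the
    BUN-to-creatinine ratio.  A cell is defined where both inputs are
    observed and the denominator is nonzero; zero denominators leave
    the cell missing with a logged warning.  Intended to run after
    binning and before imputation/normalization.
    """
    out = series.copy()
    idx = {v: i for i, v in enumerate(series.variables)}
    new_rows, new_masks, new_names = [], [], []
    for name, num, den in markers:
        if num not in idx or den not in idx:
            if require:
                raise ValueError(f"marker {name!r} needs variables {num!r} and {den!r}")
            continue
        both = series.observed_mask[idx[num]] & series.observed_mask[idx[den]]
        denom = series.values[idx[den]]
        zero = both & (denom == 0)
        if np.any(zero):
            logger.warning(
                "patient %s: %s has %d bins with zero denominator; marked missing",
                series.patient_id, name, int(zero.sum()),
            )
        ok = both & (denom != 0)
        if not np.any(ok):
            logger.warning(
                "patient %s: marker %s has no bin where both inputs are "
                "observed; marker not added", series.patient_id, name,
            )
            continue
        row = np.full(series.n_bins, np.nan)
        row[ok] = series.values[idx[num], ok] / denom[ok]
        new_rows.append(row)
        new_masks.append(ok)
        new_names.append(name)
    if new_rows:
        out.variables = list(out.variables) + new_names
        out.values = np.vstack([out.values, np.array(new_rows)])
        out.observed_mask = np.vstack([out.observed_mask, np.array(new_masks)])
    return out


def suspected_infection_times(tl: TreatmentTimeline) -> list[float]:
    """Infection-suspected timestamps (IST) from a treatment timeline.

    A timestamp is an IST if (rule 1) it is an antibiotic administration
    within 72 h after any prior body-fluid sampling, or (rule 2) a fluid
    sampling within 24 h after any prior antibiotic administration.
    Intervals are closed and equal timestamps count as prior.
    """
    ab = np.asarray(tl.antibiotic_times)
    fl = np.asarray(tl.fluid_sampling_times)
    ists: set[float] = set()
    for ta in ab:
        if np.any((fl <= ta) & (ta - fl <= ANTIBIOTIC_AFTER_FLUID_H)):
            ists.add(float(ta))
    for tf in fl:
        if np.any((ab <= tf) & (tf - ab <= FLUID_AFTER_ANTIBIOTIC_H)):
            ists.add(float(tf))
    return sorted(ists)


def annotate_onset(
    ists: Sequence[float],
    criterion: Callable[[float, float], bool],
) -> float | None:
    """Earliest onset time implied by the ISTs under a window criterion.

    For each IST (ascending) the caller-supplied ``criterion`` is
    evaluated on the window ``[IST - 48 h, IST + 24 h]``; the first
    satisfied window yields onset ``max(IST - 48, 0)``.  Returns None
    when no window satisfies the criterion.  The criterion stands in
    for a full Sepsis-3/SOFA evaluation, which is out of scope.
    """
    for t in sorted(ists):
        if criterion(t - ONSET_WINDOW_BEFORE_H, t + ONSET_WINDOW_AFTER_H):
            return max(t - ONSET_WINDOW_BEFORE_H, 0.0)
    return None
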