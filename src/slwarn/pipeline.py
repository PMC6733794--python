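"""End-to-end orchestration: events -> series -> traces -> cohort stats."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import BootstrapResult, bootstrap_report
from .containers import BinnedSeries, RawEventTable, TreatmentTimeline
from .indicators import (
    AutocorrelationIndicator,
    SurpriseLossIndicator,
    VarianceIndicator,
    patient_seed,
)
from .preprocessing import (
    annotate_onset,
    bin_series,
    derive_marker_variables,
    impute_stineman,
    suspected_infection_times,
    zscore_normalize,
)


@dataclass
class RunConfig:
    """Analysis settings (reference values: 18 h window at 30-min bins)."""

    m: int = 36  # moving window, bins (18 h)
    e: int = 3  # hidden trends
    horizon: int = 1  # lambda, bins (30 min)
    delta: int = 6  # SLMean smoothing, bins (3 h)
    bin_width_h: float = 0.5
    interval_draws: int = 1000  # B, prediction-interval resampling
    bootstrap_reps: int = 1000
    modes: tuple[str, ...] = ("full", "36h", "18h")
    insample: str = "predicted"
    derive_markers: bool = True
    normalize: bool = True
    truncate_at_onset: bool = True
    seed: int | None = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modes"] = list(self.modes)
        return d


def prepare_series(
    events: RawEventTable,
    timeline: TreatmentTimeline | None = None,
    criterion=None,
    config: RunConfig = RunConfig(),
) -> BinnedSeries:
    """Bin, derive markers, impute, normalize and annotate one patient.

    Onset comes from ``events.onset_time`` when present, otherwise from
    the timeline suspicion rules under ``criterion`` (default: always
    satisfied).  Septic series are truncated at the onset bin so the
    series end coincides with onset, mirroring discharge/death for
    non-sepsis patients.
    """
    series = bin_series(events, bin_width=config.bin_width_h)
    if config.derive_markers:
        series = derive_marker_variables(series)
    series = impute_stineman(series)
    if config.normalize:
        series = zscore_normalize(series)
    if series.onset_index is None and timeline is not None:
        ists = suspected_infection_times(timeline)
        onset = annotate_onset(ists, criterion or (lambda lo, hi: True))
        if onset is not None:
            series.onset_index = min(
                int(onset // config.bin_width_h), series.n_bins - 1
            )
    if config.truncate_at_onset and series.onset_index is not None:
        series = series.truncated(series.onset_index + 1)
    return series


def analyze_series(series: BinnedSeries, config: RunConfig = RunConfig()) -> dict:
    """SL, AC1 and VAR traces for one prepared series."""
    seed = patient_seed(config.seed, series.patient_id)
    sl = SurpriseLossIndicator(
        window=config.m,
        n_trends=config.e,
        horizon=config.horizon,
        smooth=config.delta,
        insample=config.insample,
        bin_width=config.bin_width_h,
        random_state=seed,
    ).fit(series.values.T, onset_index=series.onset_index, patient_id=series.patient_id)
    ac1 = AutocorrelationIndicator(window=config.m, bin_width=config.bin_width_h).fit(
        series.values.T, onset_index=series.onset_index, patient_id=series.patient_id
    )
    var = VarianceIndicator(window=config.m, bin_width=config.bin_width_h).fit(
        series.values.T, onset_index=series.onset_index, patient_id=series.patient_id
    )
    return {"sl": sl.trace_, "ac1": ac1.trace_, "var": var.trace_}


def analyze_cohort(
    patients: list,
    config: RunConfig = RunConfig(),
) -> tuple[list[tuple[BinnedSeries, dict]], dict[str, BootstrapResult]]:
    """Prepare + trace every patient, then cohort stats per indicator.

    ``patients`` holds ``RawEventTable`` or ``(RawEventTable,
    TreatmentTimeline)`` or ``(RawEventTable, TreatmentTimeline, meta)``
    entries.  Returns the per-patient (series, traces) list and one
    :class:`BootstrapResult` per indicator kind.
    """
    prepared = []
    for entry in patients:
        if isinstance(entry, RawEventTable):
            events, timeline = entry, None
        else:
            events, timeline = entry[0], entry[1]
        series = prepare_series(events, timeline, config=config)
        prepared.append((series, analyze_series(series, config)))

    ss = np.random.SeedSequence(config.seed)
    results = {}
    for kind, child in zip(("sl", "ac1", "var"), ss.spawn(3)):
        cohort = [(series, traces[kind]) for series, traces in prepared]
        results[kind] = bootstrap_report(
            cohort,
            modes=config.modes,
            reps=config.bootstrap_reps,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
    return prepared, results
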