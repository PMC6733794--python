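"""In-memory containers for patient time-series data.

The pipeline moves per-patient data through three representations: raw
irregular chart/lab events (:class:`RawEventTable`), treatment timestamp
lists used for onset annotation (:class:`TreatmentTimeline`), and regular
binned multivariate series (:class:`BinnedSeries`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("variable", "time_h", "value")


@dataclass
class RawEventTable:
    """Irregular long-format events for one ICU stay.

    Parameters
    ----------
    patient_id : str
        Opaque identifier (one ICU admission).
    records : pandas.DataFrame
        Columns ``variable`` (str), ``time_h`` (hours from ICU admission,
        >= 0) and ``value`` (float).
    onset_time : float or None
        Clinically annotated onset (hours), if known.
    condition_label : str or None
        Cohort label, e.g. ``"septic_shock"`` or ``"non_sepsis"``.
    meta : dict
        Free-form ground-truth/bookkeeping metadata.
    """

    patient_id: str
    records: pd.DataFrame
    onset_time: float | None = None
    condition_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")

    @classmethod
    def from_records(
        cls,
        patient_id: str,
        records: Sequence[tuple[str, float, float]],
        **kwargs,
    ) -> "RawEventTable":
        df = pd.DataFrame(list(records), columns=list(EVENT_COLUMNS))
        return cls(patient_id, df, **kwargs)


@dataclass
class TreatmentTimeline:
    """Antibiotic-administration and body-fluid-sampling timestamps (hours)."""

    patient_id: str
    antibiotic_times: list[float] = field(default_factory=list)
    fluid_sampling_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.antibiotic_times = sorted(float(t) for t in self.antibiotic_times)
        self.fluid_sampling_times = sorted(float(t) for t in self.fluid_sampling_times)
        for t in self.antibiotic_times + self.fluid_sampling_times:
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"timeline times must be finite and >= 0, got {t}")


@dataclass
class BinnedSeries:
    """Regular n-variable x T-bin matrix for one patient.

    Bin ``b`` covers the half-open interval ``[t0 + bin_width*b,
    t0 + bin_width*(b+1))``.  ``observed_mask`` is True exactly at bins
    that received at least one raw record; imputation fills values but
    never touches the mask.
    """

    patient_id: str
    variables: list[str]
    values: np.ndarray  # (n, T) float
    observed_mask: np.ndarray  # (n, T) bool
    bin_width: float = 0.5
    t0: float = 0.0
    onset_index: int | None = None
    condition_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_variables, n_bins) array")
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        if len(self.variables) != self.values.shape[0]:
            raise ValueError("len(variables) must match values.shape[0]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_times(self) -> np.ndarray:
        """Left edge of every bin, in hours from admission."""
        return self.t0 + self.bin_width * np.arange(self.n_bins)

    def copy(self) -> "BinnedSeries":
        return replace(
            self,
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
            variables=list(self.variables),
            meta=dict(self.meta),
        )

    def truncated(self, n_bins: int) -> "BinnedSeries":
        """Return a copy keeping only the first ``n_bins`` bins."""
        if not 1 <= n_bins <= self.n_bins:
            raise ValueError("n_bins out of range")
        out = self.copy()
        out.values = out.values[:, :n_bins]
        out.observed_mask = out.observed_mask[:, :n_bins]
        if out.onset_index is not None and out.onset_index >= n_bins:
            out.onset_index = n_bins - 1
        return out
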