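"""Plain-text I/O: long-format event CSVs, trace exports, parameter dumps."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinnedSeries, RawEventTable, TreatmentTimeline
from .ssm import SSMParams

EVENT_COLS = ["patient_id", "variable", "time_h", "value"]
TIMELINE_COLS = ["patient_id", "event_type", "time_h"]


def write_events_csv(tables: list[RawEventTable], path) -> None:
    frames = []
    for t in tables:
        df = t.records.copy()
        df.insert(0, "patient_id", t.patient_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True)[EVENT_COLS].to_csv(path, index=False)


def read_events_csv(path, labels: pd.DataFrame | None = None) -> list[RawEventTable]:
    """Read long-format events; optional labels frame carries
    ``patient_id``, ``condition`` and ``onset_h`` columns."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns {sorted(missing)}")
    label_map = {}
    if labels is not None:
        for _, row in labels.iterrows():
            onset = row.get("onset_h")
            label_map[str(row["patient_id"])] = (
                row.get("condition"),
                None if pd.isna(onset) else float(onset),
            )
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        cond, onset = label_map.get(str(pid), (None, None))
        out.append(
            RawEventTable(
                patient_id=str(pid),
                records=grp[["variable", "time_h", "value"]].reset_index(drop=True),
                onset_time=onset,
                condition_label=cond,
            )
        )
    return out


def write_labels_csv(tables: list[RawEventTable], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in tables],
            "condition": [t.condition_label for t in tables],
            "onset_h": [t.onset_time for t in tables],
        }
    ).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_timelines_csv(timelines: list[TreatmentTimeline], path) -> None:
    rows = []
    for tl in timelines:
        rows += [(tl.patient_id, "antibiotic", t) for t in tl.antibiotic_times]
        rows += [(tl.patient_id, "fluid", t) for t in tl.fluid_sampling_times]
    pd.DataFrame(rows, columns=TIMELINE_COLS).to_csv(path, index=False)


def read_timelines_csv(path) -> dict[str, TreatmentTimeline]:
    df = pd.read_csv(path)
    out = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        out[str(pid)] = TreatmentTimeline(
            patient_id=str(pid),
            antibiotic_times=grp.loc[grp.event_type == "antibiotic", "time_h"].tolist(),
            fluid_sampling_times=grp.loc[grp.event_type == "fluid", "time_h"].tolist(),
        )
    return out


def binned_to_frame(series: BinnedSeries) -> pd.DataFrame:
    n, T = series.values.shape
    return pd.DataFrame(
        {
            "patient_id": series.patient_id,
            "variable": np.repeat(series.variables, T),
            "bin_index": np.tile(np.arange(T), n),
            "value": series.values.ravel(),
            "observed": series.observed_mask.ravel(),
        }
    )


def trace_frame(series: BinnedSeries, traces: dict) -> pd.DataFrame:
    """Tidy per-index export of the SL/AC1/VAR traces of one patient."""
    sl = traces["sl"]
    T = sl.sl.size
    return pd.DataFrame(
        {
            "patient_id": series.patient_id,
            "index": np.arange(T),
            "time_h": series.t0 + series.bin_width * np.arange(T),
            "sl": sl.sl,
            "slmean": sl.slmean,
            "ac1": traces["ac1"].values,
            "var": traces["var"].values,
        }
    )


def tmax_frame(prepared: list[tuple[BinnedSeries, dict]]) -> pd.DataFrame:
    """Per-patient t_max summary (hours, and offset from series end)."""
    rows = []
    for series, traces in prepared:
        sl = traces["sl"]
        end_h = series.bin_width * (series.n_bins - 1)
        rows.append(
            {
                "patient_id": series.patient_id,
                "condition": series.condition_label,
                "t_max_bin": sl.t_max,
                "t_max_h": None if sl.t_max is None else sl.t_max * series.bin_width,
                "t_max_minus_T_h": None
                if sl.t_max is None
                else sl.t_max * series.bin_width - end_h,
                "t_max_ac1_bin": traces["ac1"].t_max,
                "t_max_var_bin": traces["var"].t_max,
                "dev_up_h": None
                if sl.t_max_up is None
                else (sl.t_max_up - sl.t_max) * series.bin_width,
                "dev_low_h": None
                if sl.t_max_low is None
                else (sl.t_max_low - sl.t_max) * series.bin_width,
            }
        )
    return pd.DataFrame(rows)


def params_to_text(params: SSMParams, path) -> None:
    """Flat key=value dump (matrices row-major) for reproducibility."""
    lines = [f"n={params.n}", f"e={params.e}"]
    for name in ("Z", "a", "Q", "R", "pi", "Lambda"):
        arr = np.asarray(getattr(params, name), dtype=float).ravel()
        lines.append(f"{name}=" + ",".join(repr(float(v)) for v in arr))
    Path(path).write_text("\n".join(lines) + "\n")


def params_from_text(path) -> SSMParams:
    kv = {}
    for line in Path(path).read_text().strip().splitlines():
        key, val = line.split("=", 1)
        kv[key] = val
    n, e = int(kv["n"]), int(kv["e"])
    arr = {k: np.array([float(x) for x in kv[k].split(",")]) for k in
           ("Z", "a", "Q", "R", "pi", "Lambda")}
    return SSMParams(
        Z=arr["Z"].reshape(n, e),
        a=arr["a"],
        Q=arr["Q"].reshape(e, e),
        R=arr["R"].reshape(n, n),
        pi=arr["pi"],
        Lambda=arr["Lambda"].reshape(e, e),
    )


def write_manifest(path, config: dict, seed, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {"version": __version__, "seed": seed, "config": config}
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
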