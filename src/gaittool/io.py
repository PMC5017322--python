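"""File readers and writers.

Formats are deliberately plain: trace CSV with header
``time_s,ap_g,ml_g,v_g``; gates CSV with header ``event,time_s`` (one
``start`` and one ``end`` row); profiles and ground truth as JSON with
snake_case keys.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .errors import GateOrderError, TraceFormatError
from .model import PROFILE_FIELDS, AccelerationTrace, GaitProfile, GateEvents, StepCountResult

TRACE_COLUMNS = ("time_s", "ap_g", "ml_g", "v_g")


def read_trace(path, sample_rate: float = 100.0) -> AccelerationTrace:
    """Read a tri-axial acceleration trace from CSV.

    Columns are matched by header name, so order is irrelevant.  Rows are
    sorted by time and the uniform-sampling invariant is enforced by the
    returned :class:`AccelerationTrace`.
    """
    df = pd.read_csv(path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"trace file {path} is missing column {col!r}")
    df = df.sort_values("time_s", kind="stable")
    return AccelerationTrace(
        sample_rate=sample_rate,
        time=df["time_s"].to_numpy(float),
        ap=df["ap_g"].to_numpy(float),
        ml=df["ml_g"].to_numpy(float),
        v=df["v_g"].to_numpy(float),
    )


def write_trace(trace: AccelerationTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "ap_g": trace.ap, "ml_g": trace.ml, "v_g": trace.v}
    ).to_csv(path, index=False, float_format="%.6f")


def read_gates(path) -> GateEvents:
    """Read start/end gate crossings from CSV (columns ``event,time_s``)."""
    df = pd.read_csv(path)
    for col in ("event", "time_s"):
        if col not in df.columns:
            raise TraceFormatError(f"gates file {path} is missing column {col!r}")
    events: dict[str, float] = {}
    for _, row in df.iterrows():
        label = str(row["event"]).strip().lower()
        if label not in ("start", "end"):
            raise TraceFormatError(f"unknown gate event {label!r} in {path}")
        if label in events:
            raise TraceFormatError(f"duplicate {label!r} event in {path}")
        events[label] = float(row["time_s"])
    missing = {"start", "end"} - events.keys()
    if missing:
        raise TraceFormatError(f"gates file {path} is missing event(s): {sorted(missing)}")
    if events["end"] <= events["start"]:
        raise GateOrderError(
            f"end-line time ({events['end']}) must exceed start-line time ({events['start']})"
        )
    return GateEvents(t_start=events["start"], t_end=events["end"], source="gate")


def write_gates(gates: GateEvents, path) -> None:
    pd.DataFrame(
        {"event": ["start", "end"], "time_s": [gates.t_start, gates.t_end]}
    ).to_csv(path, index=False, float_format="%.6f")


def write_profile(profile: GaitProfile, path) -> None:
    """Write a gait profile as a JSON report (NaN rendered as null)."""
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory, expected a file path")
    payload = {
        k: (None if math.isnan(v) else round(v, 6)) for k, v in profile.as_dict().items()
    }
    if profile.warnings:
        payload["quality_warnings"] = list(profile.warnings)
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_profile(path) -> dict:
    """Read a profile JSON back as a dict (missing values as NaN)."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for key in PROFILE_FIELDS:
        val = payload.get(key)
        out[key] = float("nan") if val is None else float(val)
    return out


def profile_from_dict(d: dict) -> GaitProfile:
    """Rebuild a GaitProfile from a flat dict (e.g. a read-back report).

    The nested step-count detail is not serialized; ``total_steps`` is
    carried via a minimal StepCountResult so round-trips preserve it.
    """
    total = float(d.get("total_steps", float("nan")))
    steps = None
    if not math.isnan(total):
        steps = StepCountResult(
            integer_step_count=int(total),
            initial_step_fraction=total - int(total),
            last_step_fraction=0.0,
            total_step_count=total,
            peak_times=[],
            mean_step_interval_s=1.0,
        )
    kwargs = {k: float(d[k]) for k in PROFILE_FIELDS if k != "total_steps"}
    return GaitProfile(steps=steps, **kwargs)
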