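"""Readers and writers for traces, rating series and 2x2 count tables.

Trace dialect: a CSV with columns ``stimulus_index,stim_time_s,latency_ms``
(an empty latency cell marks a conduction failure) plus a JSON sidecar with
fiber metadata and the event log.  A single-file JSON variant carries the
same content.  All files are UTF-8, comma-separated, dot-decimal, with a
mandatory header row.  Validation runs eagerly: a malformed or
invariant-violating file raises before any analysis stage sees it.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from pruricode.types import (
    Event,
    EventLog,
    LatencyTrace,
    RatingSeries,
    ValidationError,
    as_rating_tuple,
)

TRACE_COLUMNS = ["stimulus_index", "stim_time_s", "latency_ms"]
RATING_COLUMNS = ["subject_id", "substance", "application_mode", "t_s", "itch_nrs", "pain_nrs"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def _events_from_json(entries: list[dict]) -> EventLog:
    events = tuple(
        Event(
            kind=e["kind"],
            t_start=float(e["t_start_s"]),
            t_end=float(e["t_end_s"]),
            magnitude=None if e.get("magnitude") is None else float(e["magnitude"]),
        )
        for e in entries
    )
    return EventLog(entries=events)


def _events_to_json(events: EventLog) -> list[dict]:
    return [
        {
            "kind": e.kind,
            "t_start_s": e.t_start,
            "t_end_s": e.t_end,
            "magnitude": e.magnitude,
        }
        for e in events.entries
    ]


def read_latency_trace(path: str | Path, format: str = "csv") -> LatencyTrace:
    """Read one latency trace (CSV + sidecar JSON, or single JSON file)."""
    path = Path(path)
    if format == "csv":
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"{path}: cannot parse trace CSV: {exc}") from exc
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        for col in ("stim_time_s",):
            bad = frame.index[frame[col].isna()]
            if len(bad):
                # +2: header line plus 1-based numbering
                raise ValidationError(
                    f"{path}: malformed row at line {int(bad[0]) + 2}: empty {col}"
                )
        meta = json.loads(_sidecar_path(path).read_text())
    elif format == "json":
        data = json.loads(path.read_text())
        frame = pd.DataFrame(data["samples"], columns=TRACE_COLUMNS)
        meta = data
    else:
        raise ValueError(f"unknown trace format {format!r}")

    latencies = frame["latency_ms"].to_numpy(dtype=float)
    return LatencyTrace(
        fiber_id=str(meta["fiber_id"]),
        stimulus_times=frame["stim_time_s"].to_numpy(dtype=float),
        latencies=latencies,
        conduction_distance_mm=float(meta["conduction_distance_mm"]),
        events=_events_from_json(meta.get("events", [])),
    )


def write_latency_trace(trace: LatencyTrace, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    samples = pd.DataFrame(
        {
            "stimulus_index": np.arange(trace.n_stimuli, dtype=int),
            "stim_time_s": trace.stimulus_times,
            "latency_ms": trace.latencies,
        }
    )
    meta = {
        "fiber_id": trace.fiber_id,
        "conduction_distance_mm": trace.conduction_distance_mm,
        "events": _events_to_json(trace.events),
    }
    if format == "csv":
        # %.17g guarantees exact float round-trips
        samples.to_csv(path, index=False, float_format="%.17g")
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    elif format == "json":
        records = samples.where(samples.notna(), None).values.tolist()
        meta = dict(meta)
        meta["samples"] = [
            [int(i), float(t), None if l is None or (isinstance(l, float) and math.isnan(l)) else float(l)]
            for i, t, l in records
        ]
        path.write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unknown trace format {format!r}")


def read_rating_series(path: str | Path) -> List[RatingSeries]:
    """Read a rating CSV into per-(subject, substance, mode, condition) series."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if "condition" not in frame.columns:
        frame = frame.assign(condition="control")
    series: List[RatingSeries] = []
    keys = ["subject_id", "substance", "application_mode", "condition"]
    for (subject, substance, mode, condition), grp in frame.groupby(keys, sort=True):
        grp = grp.sort_values("t_s")
        series.append(
            RatingSeries(
                subject_id=str(subject),
                substance=str(substance),
                application_mode=str(mode),
                condition=str(condition),
                times_s=tuple(float(t) for t in grp["t_s"]),
                itch=as_rating_tuple(grp["itch_nrs"]),
                pain=as_rating_tuple(grp["pain_nrs"]),
            )
        )
    return series


def write_rating_series(series: Iterable[RatingSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, itch, pain in zip(s.times_s, s.itch, s.pain):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "substance": s.substance,
                    "application_mode": s.application_mode,
                    "condition": s.condition,
                    "t_s": t,
                    "itch_nrs": itch,
                    "pain_nrs": pain,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_tables(path: str | Path) -> list[dict]:
    """Read 2x2 count tables from JSON.

    Each entry: ``{label, a, b, c, d}`` with a = responders of group 1,
    b = non-responders of group 1, and c, d likewise for group 2.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("tables", [data])
    tables = []
    for i, entry in enumerate(data):
        for key in ("label", "a", "b", "c", "d"):
            if key not in entry:
                raise ValidationError(f"{path}: table {i} missing key {key!r}")
        tables.append(
            {
                "label": str(entry["label"]),
                "a": int(entry["a"]),
                "b": int(entry["b"]),
                "c": int(entry["c"]),
                "d": int(entry["d"]),
                **{k: v for k, v in entry.items() if k not in ("label", "a", "b", "c", "d")},
            }
        )
    return tables
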