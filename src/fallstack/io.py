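"""Readers and writers for sensor logs, annotations, models, and reports.

All delimited files are comma-separated UTF-8 with one header line and "."
as decimal mark. Readers validate and reject malformed input rather than
repairing it; every writer emits files its reader accepts and that
round-trip to full floating-point precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd

from .types import AnnotationEvent, SensorStream, check_no_overlap

STREAM_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
ANNOTATION_COLUMNS = [
    "subject",
    "population",
    "label",
    "is_fall",
    "location",
    "t_start_s",
    "t_end_s",
]

# %.17g round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


def write_stream(stream: SensorStream, path: str | Path) -> None:
    """Write a :class:`SensorStream` as a CSV sensor log."""
    df = pd.DataFrame(
        np.column_stack([stream.timestamps, stream.accel, stream.gyro]),
        columns=STREAM_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_stream(
    path: str | Path, subject: str = "", population: str = "control"
) -> SensorStream:
    """Read a CSV sensor log.

    Raises
    ------
    ValueError
        On a missing/misnamed header, a malformed row (with its line
        number), or non-monotone timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path, header=0, float_precision="round_trip")
    if list(df.columns) != STREAM_COLUMNS:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match "
            f"expected {STREAM_COLUMNS}"
        )
    values = df.to_numpy()
    bad = ~np.all(np.isfinite(values.astype(float, copy=False)), axis=1) \
        if values.dtype.kind == "f" else None
    if values.dtype.kind != "f":
        # a non-numeric cell somewhere: locate the first offending line
        for i, row in enumerate(values):
            try:
                np.asarray(row, dtype=float)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: malformed row at line {i + 2}") from None
        values = values.astype(float)
        bad = ~np.all(np.isfinite(values), axis=1)
    if bad is not None and bad.any():
        line = int(np.argmax(bad)) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed row at line {line}")
    t = values[:, 0]
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise ValueError(
            f"{path}: non-monotone timestamp at line {line} "
            "(duplicated or out-of-order time)"
        )
    return SensorStream(
        subject=subject,
        population=population,
        timestamps=t,
        accel=values[:, 1:4],
        gyro=values[:, 4:7],
    )


def write_annotations(events: list[AnnotationEvent], path: str | Path) -> None:
    rows = [
        {
            "subject": ev.subject,
            "population": ev.population,
            "label": ev.label,
            "is_fall": int(ev.is_fall),
            "location": ev.location,
            "t_start_s": ev.t_start,
            "t_end_s": ev.t_end,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_annotations(path: str | Path) -> list[AnnotationEvent]:
    """Read an annotation CSV; rejects overlapping events and bad intervals."""
    path = Path(path)
    df = pd.read_csv(path, header=0, float_precision="round_trip")
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match "
            f"expected {ANNOTATION_COLUMNS}"
        )
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                AnnotationEvent(
                    subject=str(row["subject"]),
                    population=str(row["population"]),
                    label=str(row["label"]),
                    is_fall=bool(int(row["is_fall"])),
                    location=str(row["location"]),
                    t_start=float(row["t_start_s"]),
                    t_end=float(row["t_end_s"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from None
    check_no_overlap(events)
    return events


def save_model(model: Any, path: str | Path) -> None:
    """Persist a fitted detector (stacked or threshold) to disk.

    The archive wraps the model with a format-version tag so stale archives
    are rejected on load instead of silently mis-predicting.
    """
    joblib.dump({"format_version": 1, "model": model}, path, compress=0)


def load_model(path: str | Path) -> Any:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format_version") != 1:
        raise ValueError(f"{path}: not a recognized model archive")
    return payload["model"]


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write an evaluation report as deterministic, sorted-key JSON."""
    Path(path).write_text(
        json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n"
    )


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
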