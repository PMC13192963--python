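"""Reading and writing traces and event tables in plain formats.

Supported trace formats
-----------------------
delimited
    Comma- or tab-separated text, optional single header line, with either a
    single ``current_nA`` column (sampling rate must be supplied) or two
    columns ``time_s,current_nA`` (sampling rate inferred from the median
    time step; any step deviating more than 1% from the median is rejected).
raw_float
    Little-endian 32-bit floats, one sample after another, with a flat
    ``key=value`` metadata sidecar ``<basename>.meta`` carrying ``fs=<Hz>``
    and optionally ``label=<text>``.

Event tables are comma-separated with columns
``event_id,start_index,end_index,t_start_s,t_end_s,dwell_s,detector``.
"""

from __future__ import annotations

import logging
import os
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    ConsistencyError,
    CurrentTrace,
    EventInterval,
    EventTable,
    FormatError,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "event_id",
    "start_index",
    "end_index",
    "t_start_s",
    "t_end_s",
    "dwell_s",
    "detector",
]

_REL_STEP_TOL = 0.01  # max fractional deviation of a time step from the median


def _sidecar_path(path: str | os.PathLike) -> Path:
    return Path(path).with_suffix(".meta")


def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    if path.exists():
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or "=" not in line:
                continue
            key, value = line.split("=", 1)
            meta[key.strip()] = value.strip()
    return meta


def read_trace(
    path: str | os.PathLike,
    format: str = "delimited",
    fs: float | None = None,
    label: str | None = None,
) -> CurrentTrace:
    """Read a current trace from disk.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"delimited"`` or ``"raw_float"``.
    fs:
        Sampling rate in Hz. Required for ``raw_float`` without a sidecar and
        for single-column delimited files; ignored when a time column is
        present (it is inferred from the median step instead).
    label:
        Optional dataset tag; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if label is None:
        label = path.stem

    if format == "raw_float":
        meta = _read_sidecar(_sidecar_path(path))
        if fs is None:
            if "fs" not in meta:
                raise ConfigurationError(
                    "raw_float requires fs, either as an argument or in the "
                    f"sidecar {_sidecar_path(path)}"
                )
            fs = float(meta["fs"])
        label = meta.get("label", label)
        data = np.fromfile(path, dtype="<f4").astype(np.float64)
        if data.size == 0:
            raise FormatError(f"empty raw_float file: {path}")
        finite = np.isfinite(data)
        if not finite.all():
            logger.warning(
                "dropping %d non-finite samples from %s", (~finite).sum(), path
            )
            data = data[finite]
        if data.size == 0:
            raise FormatError(f"no finite samples in {path}")
        return CurrentTrace(data, fs=fs, label=label)

    if format != "delimited":
        raise ConfigurationError(f"unknown trace format {format!r}")

    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty file: {path}")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0]
    has_header = False
    for token in first.split(sep):
        try:
            float(token)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(
        StringIO(text), sep=sep, header=0 if has_header else None, comment="#"
    )
    if df.shape[1] not in (1, 2):
        raise FormatError(
            f"expected 1 (current) or 2 (time,current) columns, got {df.shape[1]}"
        )
    values = df.to_numpy(dtype=np.float64)
    finite = np.isfinite(values).all(axis=1)
    if not finite.all():
        logger.warning("dropping %d non-finite rows from %s", (~finite).sum(), path)
        values = values[finite]
    if values.shape[0] == 0:
        raise FormatError(f"no finite rows in {path}")

    if values.shape[1] == 1:
        if fs is None:
            raise ConfigurationError(
                "single-column delimited trace requires an explicit fs"
            )
        return CurrentTrace(values[:, 0], fs=fs, label=label)

    t, current = values[:, 0], values[:, 1]
    if t.size < 2:
        raise FormatError("time,current file needs at least 2 rows to infer fs")
    steps = np.diff(t)
    med = float(np.median(steps))
    if med <= 0:
        raise FormatError("time column is not increasing")
    if np.any(np.abs(steps - med) > _REL_STEP_TOL * med):
        raise FormatError(
            "non-uniform time column: a step deviates more than 1% from the median"
        )
    return CurrentTrace(current, fs=1.0 / med, label=label)


def write_trace(
    trace: CurrentTrace,
    path: str | os.PathLike,
    format: str = "delimited",
    with_time: bool = True,
) -> None:
    """Write a trace to disk; inverse of :func:`read_trace`.

    Delimited output prints 9 significant digits, so a delimited round trip
    preserves samples to that precision. ``raw_float`` writes little-endian
    float32 plus a ``.meta`` sidecar with ``fs`` and ``label``.
    """
    path = Path(path)
    if format == "raw_float":
        trace.samples.astype("<f4").tofile(path)
        _sidecar_path(path).write_text(f"fs={trace.fs!r}\nlabel={trace.label}\n")
        return
    if format != "delimited":
        raise ConfigurationError(f"unknown trace format {format!r}")
    with open(path, "w") as fh:
        if with_time:
            fh.write("time_s,current_nA\n")
            for k, x in enumerate(trace.samples):
                fh.write(f"{k / trace.fs:.9g},{x:.9g}\n")
        else:
            fh.write("current_nA\n")
            for x in trace.samples:
                fh.write(f"{x:.9g}\n")


def events_to_frame(table: EventTable, trace: CurrentTrace) -> pd.DataFrame:
    """Event table as a DataFrame with times derived from the trace's fs."""
    table.validate_against(trace)
    rows = []
    for i, ev in enumerate(table.events):
        rows.append(
            {
                "event_id": i,
                "start_index": ev.start,
                "end_index": ev.end,
                "t_start_s": ev.start / trace.fs,
                "t_end_s": ev.end / trace.fs,
                "dwell_s": (ev.end - ev.start) / trace.fs,
                "detector": ev.detector,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(
    table: EventTable, trace: CurrentTrace, path: str | os.PathLike
) -> None:
    """Write an event table as CSV; raises if events exceed the trace."""
    events_to_frame(table, trace).to_csv(path, index=False)


def read_events(path: str | os.PathLike, trace_label: str = "") -> EventTable:
    """Read an event table written by :func:`write_events` (bit-exact indices)."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns: {sorted(missing)}")
    events = [
        EventInterval(int(r.start_index), int(r.end_index), str(r.detector))
        for r in df.itertuples()
    ]
    return EventTable(events=events, trace_label=trace_label)
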