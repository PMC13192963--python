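"""Core data model: current traces and event intervals.

Conventions used throughout the package:

* indexing is 0-based; event intervals are half-open ``[start, end)`` so that
  the dwell in samples is exactly ``end - start``;
* the time of sample ``k`` is ``k / fs`` seconds;
* traces are stored as recorded, and detectors treat blockades as *downward*
  excursions (current drops below the open-pore baseline) unless a polarity
  option says otherwise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CurrentTrace",
    "EventInterval",
    "EventTable",
    "PorecallError",
    "ConfigurationError",
    "FormatError",
    "ConsistencyError",
    "InputError",
    "DegenerateFitError",
    "ThresholdFallbackError",
    "config_digest",
]


class PorecallError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PorecallError):
    """A configuration value is missing, out of range or inconsistent."""


class FormatError(PorecallError):
    """An on-disk file does not conform to a supported format."""


class ConsistencyError(PorecallError):
    """Two objects that must agree (e.g. events vs. trace length) do not."""


class InputError(PorecallError):
    """An input violates an operation's precondition (e.g. too short)."""


class DegenerateFitError(PorecallError):
    """The two-component mixture fit collapsed; the adaptive detector is the
    recommended fallback for such traces."""


class ThresholdFallbackError(PorecallError):
    """No valid valley threshold exists between the component means; the
    adaptive detector is the recommended fallback."""


@dataclass(frozen=True)
class CurrentTrace:
    """A uniformly sampled single-channel ionic-current recording.

    Parameters
    ----------
    samples:
        Current values in nA. Stored as a read-only float64 array.
    fs:
        Sampling rate in Hz (> 0). Sample ``k`` is at time ``k / fs``.
    label:
        Free-text dataset tag.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise InputError("trace must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(arr)):
            raise InputError("trace samples must all be finite")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        """Time stamps in seconds, ``k / fs`` for each sample."""
        return np.arange(len(self)) / self.fs

    def flipped(self) -> "CurrentTrace":
        """Return the trace with inverted sign (for upward-blockade data)."""
        return CurrentTrace(-self.samples, self.fs, self.label)


DETECTOR_NAMES = ("cbed", "cbed_adaptive", "cusum", "pelt", "truth")


@dataclass(frozen=True, order=True)
class EventInterval:
    """A half-open sample-index interval ``[start, end)`` flagged as a blockade."""

    start: int
    end: int
    detector: str = "cbed"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConsistencyError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.detector not in DETECTOR_NAMES:
            raise ConfigurationError(
                f"unknown detector {self.detector!r}; expected one of {DETECTOR_NAMES}"
            )

    @property
    def dwell_samples(self) -> int:
        return self.end - self.start

    def overlap(self, other: "EventInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class EventTable:
    """An ordered, non-overlapping collection of detected (or true) events."""

    events: list[EventInterval] = field(default_factory=list)
    trace_label: str = ""
    config_digest: str = ""

    def __post_init__(self) -> None:
        ev = sorted(self.events)
        for a, b in zip(ev, ev[1:]):
            if a.end > b.start:
                raise ConsistencyError(
                    f"overlapping events [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def validate_against(self, trace: CurrentTrace) -> None:
        if self.events and self.events[-1].end > len(trace):
            raise ConsistencyError(
                f"event end {self.events[-1].end} exceeds trace length {len(trace)}"
            )

    def starts_ends(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([e.start for e in self.events], dtype=np.int64)
        e = np.array([e.end for e in self.events], dtype=np.int64)
        return s, e


def intervals_to_table(
    intervals: Iterable[tuple[int, int]],
    detector: str,
    trace_label: str = "",
    config_digest: str = "",
) -> EventTable:
    """Build an :class:`EventTable` from ``(start, end)`` pairs."""
    return EventTable(
        events=[EventInterval(int(a), int(b), detector) for a, b in intervals],
        trace_label=trace_label,
        config_digest=config_digest,
    )


def config_digest(obj: object) -> str:
    """Short, stable fingerprint of a configuration object.

    Uses the sorted ``repr`` of the object's dataclass fields (or the object
    itself), hashed with SHA-1 and truncated to 12 hex characters.
    """
    if hasattr(obj, "__dataclass_fields__"):
        items = sorted(
            (name, repr(getattr(obj, name))) for name in obj.__dataclass_fields__
        )
        text = ";".join(f"{k}={v}" for k, v in items)
        text = type(obj).__name__ + ":" + text
    else:
        text = repr(obj)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def runs_from_mask(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open intervals."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = list(edges[m[edges + 1]] + 1)
    ends = list(edges[~m[edges + 1]] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))
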