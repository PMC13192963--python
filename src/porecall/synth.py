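"""Synthetic traces with known ground truth.

The generator emulates the regimes seen in solid-state and biological pore
recordings: a constant open-pore baseline with Gaussian noise, downward
rectangular blockades of configurable depth/duration, and optional slow
baseline drift (linear or sinusoidal). Rectangular two-level events keep the
ground-truth features (dwell, height, mean) analytically exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import (
    ConfigurationError,
    CurrentTrace,
    EventTable,
    InputError,
    intervals_to_table,
)

__all__ = ["Drift", "SyntheticSpec", "generate", "random_event_train", "match_events"]


@dataclass(frozen=True)
class Drift:
    """Slow baseline drift: ``none``, ``linear`` (slope in nA/s) or
    ``sinusoid`` (amplitude in nA, period in s)."""

    kind: Literal["none", "linear", "sinusoid"] = "none"
    slope: float = 0.0
    amplitude: float = 0.0
    period_s: float = 1.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(t)
        if self.kind == "linear":
            return self.slope * t
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(2 * np.pi * t / self.period_s)
        raise ConfigurationError(f"unknown drift kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a synthetic trace.

    ``events`` is a list of ``(onset_s, dwell_s, depth_nA)`` triples; depths
    are positive and subtracted from the baseline (blockades go downward).
    Events must be non-overlapping and lie inside ``[0, duration_s]``.
    """

    fs: float = 100_000.0
    duration_s: float = 1.0
    baseline: float = 1.0
    noise_sd: float = 0.02
    events: Sequence[tuple[float, float, float]] = field(default_factory=tuple)
    drift: Drift = Drift()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        ev = sorted(self.events)
        for onset, dwell, depth in ev:
            if depth <= 0:
                raise ConfigurationError(f"event depth must be > 0, got {depth}")
            if onset < 0 or onset + dwell > self.duration_s:
                raise ConfigurationError(
                    f"event ({onset}, {dwell}) not inside [0, {self.duration_s}]"
                )
        for (o1, d1, _), (o2, _, _) in zip(ev, ev[1:]):
            if o1 + d1 > o2:
                raise ConfigurationError("events overlap")
        object.__setattr__(self, "events", tuple(ev))


def _event_indices(spec: SyntheticSpec, n: int) -> list[tuple[int, int]]:
    out = []
    for onset, dwell, _ in spec.events:
        start = int(round(onset * spec.fs))
        length = max(1, int(round(dwell * spec.fs)))
        end = min(start + length, n)
        start = min(start, n - 1)
        out.append((start, end))
    return out


def generate(spec: SyntheticSpec) -> tuple[CurrentTrace, EventTable]:
    """Generate a trace and its ground-truth event table.

    ``trace[k] = baseline + drift(k/fs) - depth * 1[k in event] + N(0, noise_sd)``
    with all randomness drawn from ``numpy.random.default_rng(spec.seed)``,
    so the same spec always yields the identical trace.
    """
    n = int(round(spec.duration_s * spec.fs))
    if n < 1:
        raise ConfigurationError("duration too short for even one sample")
    t = np.arange(n) / spec.fs
    signal = spec.baseline + spec.drift(t)
    intervals = _event_indices(spec, n)
    for (start, end), (_, _, depth) in zip(intervals, spec.events):
        signal[start:end] -= depth
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n)
    trace = CurrentTrace(signal, fs=spec.fs, label=f"synthetic-seed{spec.seed}")
    truth = intervals_to_table(intervals, detector="truth", trace_label=trace.label)
    return trace, truth


def random_event_train(
    n_events: int,
    duration_s: float,
    dwell_s: float | tuple[float, float],
    depth_nA: float | tuple[float, float],
    seed: int,
    guard_s: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Place ``n_events`` non-overlapping events uniformly over the trace.

    ``dwell_s`` and ``depth_nA`` may be scalars or (low, high) ranges sampled
    uniformly. ``guard_s`` is dead time enforced between consecutive events.
    Raises if the requested events cannot fit.
    """
    rng = np.random.default_rng(seed)
    dw_lo, dw_hi = (dwell_s, dwell_s) if np.isscalar(dwell_s) else dwell_s
    dp_lo, dp_hi = (depth_nA, depth_nA) if np.isscalar(depth_nA) else depth_nA
    dwells = rng.uniform(dw_lo, dw_hi, size=n_events)
    depths = rng.uniform(dp_lo, dp_hi, size=n_events)
    slack = duration_s - dwells.sum() - guard_s * (n_events + 1)
    if slack < 0:
        raise ConfigurationError("events do not fit into the trace duration")
    # distribute the free time among the n+1 gaps via a Dirichlet-like split
    cuts = np.sort(rng.uniform(0, slack, size=n_events))
    gaps = np.diff(np.concatenate([[0.0], cuts])) + guard_s
    events = []
    cursor = 0.0
    for gap, dwell, depth in zip(gaps, dwells, depths):
        cursor += gap
        events.append((cursor, float(dwell), float(depth)))
        cursor += dwell
    return events


def match_events(
    truth: EventTable, detected: EventTable, min_overlap: float = 0.5
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected against true events.

    A detected event may match a truth event when their intersection covers at
    least ``min_overlap`` of the truth interval; pairs are matched in order of
    descending overlap, each event used at most once.

    Returns ``(true_positives, false_positives, false_negatives)``, which
    partition both tables: ``TP + FP = len(detected)``,
    ``TP + FN = len(truth)``.
    """
    if not (0 < min_overlap <= 1):
        raise ConfigurationError(f"min_overlap must be in (0, 1], got {min_overlap}")
    pairs = []
    for i, tev in enumerate(truth.events):
        for j, dev in enumerate(detected.events):
            if dev.start >= tev.end or dev.end <= tev.start:
                continue
            inter = tev.overlap(dev)
            if inter / tev.dwell_samples >= min_overlap:
                pairs.append((inter, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        tp += 1
    return tp, len(detected) - tp, len(truth) - tp
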