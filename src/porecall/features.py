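"""Per-event features and K-means clustering in the (mean, height) plane.

Three features summarise a blockade event relative to a baseline reference:

* **dwell_s** — event duration, ``(end - start) / fs``;
* **height_nA** — maximal drop below the baseline within the event (>= 0);
* **mean_nA** — average drop over the event, reported *negative* (a drop is
  a negative current change), so ``|mean_nA| <= height_nA`` always.

The baseline reference is whatever the detector that produced the events
estimated: the mixture's baseline mean for fixed-threshold CBED, the
rolling-median series for adaptive CBED, and the mean of a window of samples
just before the event for the change-point detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .model import ConsistencyError, CurrentTrace, EventTable, InputError

__all__ = [
    "EventFeatures",
    "FeatureClusters",
    "extract_features",
    "feature_table",
    "pre_event_baseline",
    "kmeans_features",
]

PRE_EVENT_WINDOW = 50  # samples of pre-event context for the baseline mean


@dataclass(frozen=True)
class EventFeatures:
    dwell_s: float
    height_nA: float
    mean_nA: float

    def __post_init__(self) -> None:
        if abs(self.mean_nA) > self.height_nA + 1e-12:
            raise ConsistencyError(
                f"|mean| = {abs(self.mean_nA)} exceeds height = {self.height_nA}"
            )


@dataclass(frozen=True)
class FeatureClusters:
    assignments: np.ndarray  # cluster label per event, in [0, k)
    centroids: np.ndarray  # (k, 2) array of (mean_nA, height_nA)
    k: int
    inertia: float


def _baseline_slice(
    baseline_ref: np.ndarray | float, start: int, end: int, n: int
) -> np.ndarray | float:
    if np.isscalar(baseline_ref):
        return float(baseline_ref)
    ref = np.asarray(baseline_ref, dtype=np.float64)
    if ref.size < n:
        raise ConsistencyError(
            f"baseline series of {ref.size} samples does not cover the trace ({n})"
        )
    return ref[start:end]


def extract_features(
    trace: CurrentTrace,
    event,
    baseline_ref: np.ndarray | float,
) -> EventFeatures:
    """Features of one event against a scalar or per-sample baseline."""
    start, end = event.start, event.end
    if end > len(trace):
        raise ConsistencyError("event exceeds trace length")
    ref = _baseline_slice(baseline_ref, start, end, len(trace))
    drop = ref - trace.samples[start:end]
    height = float(max(np.max(drop), 0.0))
    mean_drop = float(np.mean(drop))
    # an event's average drop cannot exceed its maximal drop; clip guards the
    # invariant against pathological references (e.g. below-trace baselines)
    mean = -float(np.clip(mean_drop, -height, height))
    return EventFeatures(
        dwell_s=(end - start) / trace.fs, height_nA=height, mean_nA=mean
    )


def pre_event_baseline(
    trace: CurrentTrace, events: EventTable, window: int = PRE_EVENT_WINDOW
) -> list[float]:
    """Per-event scalar baseline: mean of up to ``window`` samples before each
    event (excluding samples inside the previous event). Falls back to the
    trace median when no pre-event context exists."""
    refs: list[float] = []
    prev_end = 0
    for ev in events:
        lo = max(prev_end, ev.start - window)
        ctx = trace.samples[lo : ev.start]
        refs.append(float(np.mean(ctx)) if ctx.size else float(np.median(trace.samples)))
        prev_end = ev.end
    return refs


def feature_table(
    trace: CurrentTrace,
    events: EventTable,
    baseline_ref: np.ndarray | float | list[float],
) -> pd.DataFrame:
    """One feature row per event; ``baseline_ref`` may be a scalar, a
    per-sample series, or one scalar per event."""
    events.validate_against(trace)
    per_event = isinstance(baseline_ref, list)
    if per_event and len(baseline_ref) != len(events):
        raise ConsistencyError("per-event baseline list length mismatch")
    rows = []
    for i, ev in enumerate(events):
        ref = baseline_ref[i] if per_event else baseline_ref
        f = extract_features(trace, ev, ref)
        rows.append(
            {
                "event_id": i,
                "dwell_s": f.dwell_s,
                "height_nA": f.height_nA,
                "mean_nA": f.mean_nA,
            }
        )
    return pd.DataFrame(rows, columns=["event_id", "dwell_s", "height_nA", "mean_nA"])


def kmeans_features(
    features: list[EventFeatures] | pd.DataFrame,
    k: int,
    seed: int = 0,
    standardize: bool = False,
) -> FeatureClusters:
    """K-means on the 2-D points ``(mean_nA, height_nA)``.

    k-means++ initialisation with 10 restarts, deterministic for a given
    seed. ``standardize`` optionally z-scores the two axes first (off by
    default: the raw nA axes are the natural feature space here).
    """
    if isinstance(features, pd.DataFrame):
        pts = features[["mean_nA", "height_nA"]].to_numpy(dtype=np.float64)
    else:
        pts = np.array([[f.mean_nA, f.height_nA] for f in features], dtype=np.float64)
    if k < 1:
        raise InputError("k must be >= 1")
    if pts.shape[0] < k:
        raise InputError(f"{pts.shape[0]} events cannot support k={k} clusters")
    work = pts
    if standardize:
        sd = pts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        work = (pts - pts.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(work)
    centroids = np.vstack([pts[labels == j].mean(axis=0) for j in range(k)])
    inertia = float(((pts - centroids[labels]) ** 2).sum())
    return FeatureClusters(
        assignments=labels, centroids=centroids, k=k, inertia=inertia
    )
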