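"""Adaptive CBED for drifting baselines.

When the open-pore current drifts, the global histogram's baseline and event
clusters smear into each other and a single fixed threshold fails. The
adaptive extension replaces global clustering with four steps:

1. **Rolling-median baseline** ``B[k]``: median over a centered window of
   ``N = round(W * fs)`` samples, shrinking (never empty) at the trace edges.
2. **Baseline correction** ``C[k] = I[k] - B[k]``, a zero-centered residual.
3. **Adaptive threshold** ``T = median(C) - alpha * SD(C)`` over the whole
   corrected trace (SD with ddof = 1, alpha = 1.5 by default).
4. **Event calling**: samples with ``C[k] < T`` are candidate blockade
   points; candidates separated by at most ``delta_max`` samples are joined
   into one interval, and intervals shorter than ``ceil(fs * dt_min)``
   samples are discarded.

Because a short blockade occupies less than half of any window wider than
twice its dwell, the rolling median tracks the drifting baseline while
stepping over the events themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    ConsistencyError,
    CurrentTrace,
    EventTable,
    InputError,
    config_digest,
    intervals_to_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AdaptiveConfig",
    "rolling_median_baseline",
    "correct_baseline",
    "adaptive_threshold",
    "adaptive_events",
]


@dataclass(frozen=True)
class AdaptiveConfig:
    W: float = 0.5  # baseline window duration (s)
    alpha: float = 1.5  # threshold multiplier
    delta_max: int | None = None  # max joinable gap (samples); None -> derived
    dt_min: float = 1e-3  # minimum event duration (s)
    count_mode: Literal["span", "flagged"] = "span"

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ConfigurationError("W must be > 0 seconds")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if self.delta_max is not None and self.delta_max < 0:
            raise ConfigurationError("delta_max must be >= 0")
        if self.dt_min <= 0:
            raise ConfigurationError("dt_min must be > 0 seconds")
        if self.count_mode not in ("span", "flagged"):
            raise ConfigurationError("count_mode must be 'span' or 'flagged'")

    def resolved_delta_max(self, fs: float) -> int:
        """Default gap: 10% of the minimum event length, at least 1 sample."""
        if self.delta_max is not None:
            return self.delta_max
        nmin = math.ceil(fs * self.dt_min)
        return max(1, round(0.1 * nmin))


def rolling_median_baseline(trace: CurrentTrace, W: float) -> np.ndarray:
    """Centered rolling-median baseline with shrinking edge windows.

    The window holds ``N = round(W * fs)`` samples (for even N the window is
    ``[k - N/2, k + N/2 - 1]``); at the edges it is clipped to the trace and
    always keeps at least one sample. Even-sized windows use the mean of the
    two middle order statistics.
    """
    if W <= 0:
        raise ConfigurationError("W must be > 0 seconds")
    n_win = max(1, int(round(W * trace.fs)))
    s = pd.Series(trace.samples)
    return s.rolling(window=n_win, center=True, min_periods=1).median().to_numpy()


def correct_baseline(trace: CurrentTrace, baseline: np.ndarray) -> np.ndarray:
    """Residual ``C[k] = I[k] - B[k]``."""
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != trace.samples.shape:
        raise ConsistencyError(
            f"baseline length {baseline.size} != trace length {len(trace)}"
        )
    return trace.samples - baseline


def adaptive_threshold(C: np.ndarray, alpha: float = 1.5) -> float:
    """Threshold ``median(C) - alpha * SD(C)`` over the whole residual."""
    C = np.asarray(C, dtype=np.float64)
    if C.size < 2:
        raise InputError("residual series needs at least 2 samples")
    med = float(np.median(C))
    sd = float(np.std(C, ddof=1))
    if sd == 0.0:
        logger.warning("constant residual: SD is 0, threshold equals the median")
    return med - alpha * sd


def adaptive_events(
    trace: CurrentTrace, cfg: AdaptiveConfig = AdaptiveConfig()
) -> tuple[EventTable, np.ndarray, float]:
    """Detect events with the rolling-median baseline and adaptive threshold.

    Returns the event table, the baseline series, and the threshold (in
    residual coordinates). Flagged indices with successive gaps of at most
    ``delta_max`` samples join into one preliminary interval spanning first
    to last flagged index (half-open); intervals below the duration rule are
    discarded. ``count_mode="span"`` counts the interval's full span against
    ``ceil(fs * dt_min)``; ``"flagged"`` counts only the flagged samples.
    """
    baseline = rolling_median_baseline(trace, cfg.W)
    C = correct_baseline(trace, baseline)
    thresh = adaptive_threshold(C, cfg.alpha)
    dmax = cfg.resolved_delta_max(trace.fs)
    nmin = math.ceil(trace.fs * cfg.dt_min)
    flagged = np.flatnonzero(C < thresh)
    events: list[tuple[int, int]] = []
    if flagged.size:
        # gap = samples strictly between consecutive flagged indices
        breaks = np.flatnonzero(np.diff(flagged) - 1 > dmax)
        group_starts = np.concatenate([[0], breaks + 1])
        group_ends = np.concatenate([breaks, [flagged.size - 1]])
        for gs, ge in zip(group_starts, group_ends):
            first, last = int(flagged[gs]), int(flagged[ge])
            count = (last - first + 1) if cfg.count_mode == "span" else (ge - gs + 1)
            if count >= nmin:
                events.append((first, last + 1))
    table = intervals_to_table(
        events,
        "cbed_adaptive",
        trace_label=trace.label,
        config_digest=config_digest(cfg),
    )
    return table, baseline, thresh
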