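"""Rough event localization.

A cheap pre-filter that marks candidate event regions before the more
expensive change-point detectors run. Two modes:

* **global** — a single threshold ``sigma_thresh = n * I_RMS`` below the
  baseline mean, where ``I_RMS`` is the standard deviation of the baseline
  current; samples dropping more than ``sigma_thresh`` below the baseline
  mean are candidates.
* **local** — running mean/SD over the trailing window of (by default) 50
  baseline samples define hysteresis thresholds: a candidate opens when the
  current falls below ``mean - nS * SD`` and closes when it recovers above
  ``mean - nE * SD``. While a candidate is open the running statistics are
  frozen, so the event itself does not contaminate the local baseline.

Baseline statistics for the global mode are estimated with iterative
lower-tail sigma-clipping: samples more than 2.5 running-SDs below the
running mean are discarded and the statistics recomputed until a fixed
point. On an event-free trace no sample is clipped and the estimate is the
plain sample mean/SD; with blockades present the downward excursions are
excluded so the baseline SD is not inflated by the events themselves.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import CurrentTrace, InputError, runs_from_mask

logger = logging.getLogger(__name__)

__all__ = ["RoughConfig", "global_threshold", "localize_global", "localize_local"]

_CLIP_SIGMAS = 2.5  # lower-tail clip depth for baseline statistics
_CLIP_MAX_ITER = 20


@dataclass(frozen=True)
class RoughConfig:
    mode: Literal["global", "local"] = "global"
    n: float = 5.0  # global sensitivity multiplier
    nS: float = 6.0  # local start multiplier
    nE: float = 2.0  # local end multiplier
    window: int = 50  # samples for local statistics
    pad: int = 10  # context samples kept on each side of a region

    def __post_init__(self) -> None:
        if min(self.n, self.nS, self.nE) <= 0:
            raise InputError("n, nS, nE must all be positive")
        if self.window < 2:
            raise InputError("window must be at least 2 samples")
        if self.pad < 0:
            raise InputError("pad must be non-negative")
        if self.nS < self.nE:
            logger.warning(
                "nS (%.3g) < nE (%.3g): start threshold is shallower than end "
                "threshold; hysteresis usually wants nS >= nE",
                self.nS,
                self.nE,
            )


def _baseline_stats(trace: CurrentTrace) -> tuple[float, float]:
    """Baseline mean and SD (ddof=1) by iterative lower-tail sigma-clipping.

    Blockades are downward, so only the low tail is clipped; an event-free
    trace converges immediately to its plain sample statistics.
    """
    x = np.sort(trace.samples)
    lo = 0  # clip boundary into the sorted array
    for _ in range(_CLIP_MAX_ITER):
        kept = x[lo:]
        mean = float(np.mean(kept))
        sd = float(np.std(kept, ddof=1)) if kept.size >= 2 else 0.0
        new_lo = int(np.searchsorted(x, mean - _CLIP_SIGMAS * sd, side="left"))
        if new_lo <= lo or x.size - new_lo < 2:
            break
        lo = new_lo
    return mean, sd


def global_threshold(trace: CurrentTrace, n: float) -> float:
    """Global rough threshold ``sigma_thresh = n * I_RMS``.

    A zero-variance (constant) trace yields threshold 0 with a warning.
    """
    if len(trace) < 2:
        raise InputError("need at least 2 samples for a baseline SD")
    _, sd = _baseline_stats(trace)
    if sd == 0.0:
        logger.warning("degenerate signal: baseline I_RMS is 0, threshold is 0")
    return n * sd


def _pad_merge(
    runs: list[tuple[int, int]], pad: int, n: int
) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in runs:
        a, b = max(0, a - pad), min(n, b + pad)
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def localize_global(trace: CurrentTrace, cfg: RoughConfig) -> list[tuple[int, int]]:
    """Candidate regions from the global threshold, padded and merged."""
    thresh = global_threshold(trace, cfg.n)
    mean, _ = _baseline_stats(trace)
    mask = (mean - trace.samples) > thresh
    return _pad_merge(runs_from_mask(mask), cfg.pad, len(trace))


def localize_local(trace: CurrentTrace, cfg: RoughConfig) -> list[tuple[int, int]]:
    """Candidate regions from trailing-window hysteresis thresholds.

    The running mean and SD are computed over the last ``cfg.window`` samples
    classified as baseline; in-event samples never enter the statistics.
    Detection starts once the first full window of baseline samples exists.
    """
    x = trace.samples
    if len(x) <= cfg.window:
        raise InputError(
            f"trace length {len(x)} must exceed the local window {cfg.window}"
        )
    w = cfg.window
    buf: deque[float] = deque(maxlen=w)
    s1 = 0.0  # running sum of the buffer
    s2 = 0.0  # running sum of squares

    def push(v: float) -> None:
        nonlocal s1, s2
        if len(buf) == w:
            old = buf[0]
            s1 -= old
            s2 -= old * old
        buf.append(v)
        s1 += v
        s2 += v * v

    runs: list[tuple[int, int]] = []
    open_at: int | None = None
    eta_end = 0.0
    for k in range(len(x)):
        if len(buf) < w:
            push(x[k])
            continue
        mean = s1 / w
        var = max((s2 - w * mean * mean) / (w - 1), 0.0)
        sd = np.sqrt(var)
        if open_at is None:
            if x[k] < mean - cfg.nS * sd:
                open_at = k
                eta_end = mean - cfg.nE * sd  # statistics frozen while open
            else:
                push(x[k])
        else:
            if x[k] >= eta_end:
                runs.append((open_at, k))
                open_at = None
                push(x[k])
    if open_at is not None:
        runs.append((open_at, len(x)))
    return _pad_merge(runs, cfg.pad, len(x))
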