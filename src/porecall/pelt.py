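"""Optimal offline segmentation with PELT and a Gaussian cost.

The cost of a segment ``y[a:b]`` (half-open, n = b - a samples) is the
Gaussian negative log-likelihood up to constants,

    c(a, b) = n * ln(sigma2) + (1 / sigma2) * sum((y - mu)**2)

with ``mu`` and ``sigma2`` the segment mean and maximum-likelihood
(ddof = 0) variance, in which case the quadratic term collapses to ``n``
exactly. Variances are floored at 1e-12 nA^2 so constant segments stay
finite. Segment costs come from prefix sums in O(1).

A segmentation ``T`` minimises ``sum(c) + beta * |T|``; the PELT dynamic
program with the standard pruning inequality finds the exact global optimum.
``beta`` may be a number or ``"bic"``, in which case ``beta = 2 * ln(n)``
(two parameters, mean and variance, per additional segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    ConfigurationError,
    CurrentTrace,
    EventTable,
    InputError,
    config_digest,
    intervals_to_table,
)
from .rough import RoughConfig, localize_global, localize_local

logger = logging.getLogger(__name__)

__all__ = [
    "PeltConfig",
    "Segmentation",
    "segment_cost",
    "pelt_changepoints",
    "bic_beta",
    "pelt_events",
]

VAR_FLOOR = 1e-12  # nA^2; far below any realistic noise power


@dataclass(frozen=True)
class PeltConfig:
    beta: float | str = "bic"  # penalty per change point, or "bic"
    min_segment: int = 2

    def __post_init__(self) -> None:
        if isinstance(self.beta, str):
            if self.beta != "bic":
                raise ConfigurationError(f"beta must be a number or 'bic', got {self.beta!r}")
        elif self.beta < 0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")
        if self.min_segment < 2:
            raise ConfigurationError("min_segment must be >= 2 (variance needs 2 samples)")


@dataclass(frozen=True)
class Segmentation:
    change_points: tuple[int, ...]  # interior boundaries; 0 and n are implicit
    total_cost: float  # V(T) + beta * |T|


class _PrefixCost:
    """O(1) Gaussian segment costs from prefix sums of y and y**2."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=np.float64)
        self.c1 = np.concatenate([[0.0], np.cumsum(y)])
        self.c2 = np.concatenate([[0.0], np.cumsum(y * y)])
        self.warned = False

    def __call__(self, a: int, b: int) -> float:
        n = b - a
        s1 = self.c1[b] - self.c1[a]
        s2 = self.c2[b] - self.c2[a]
        var = max(s2 / n - (s1 / n) ** 2, 0.0)
        if var < VAR_FLOOR:
            if not self.warned:
                logger.warning("zero-variance segment; variance floored at %g", VAR_FLOOR)
                self.warned = True
            quad = (var * n) / VAR_FLOOR
            var = VAR_FLOOR
        else:
            quad = n  # ML variance makes the quadratic term exactly n
        return n * np.log(var) + quad


def segment_cost(trace: CurrentTrace | np.ndarray, a: int, b: int, min_segment: int = 2) -> float:
    """Gaussian cost of the half-open segment ``[a, b)``."""
    y = trace.samples if isinstance(trace, CurrentTrace) else np.asarray(trace)
    if b - a < min_segment:
        raise InputError(f"segment [{a}, {b}) shorter than min_segment={min_segment}")
    return float(_PrefixCost(y[a:b])(0, b - a))


def bic_beta(segment: CurrentTrace | np.ndarray) -> float:
    """Penalty ``beta = 2 * ln(n)`` (mean + variance per extra segment)."""
    n = len(segment)
    if n < 4:
        raise InputError("BIC penalty needs at least 4 samples")
    return 2.0 * np.log(n)


def pelt_changepoints(
    segment: CurrentTrace | np.ndarray, cfg: PeltConfig
) -> Segmentation:
    """Exact penalized-cost-optimal change points of a segment.

    Implements the pruned dynamic program: ``F(t) = min over admissible last
    change points tau of F(tau) + c(tau, t) + beta``, discarding a candidate
    ``tau`` once ``F(tau) + c(tau, t) > F(t)`` (the Gaussian likelihood cost
    satisfies the required subadditivity with pruning constant 0).
    """
    y = segment.samples if isinstance(segment, CurrentTrace) else np.asarray(segment)
    n = y.size
    if n < cfg.min_segment:
        raise InputError(f"segment of {n} samples is shorter than min_segment")
    beta = bic_beta(y) if cfg.beta == "bic" else float(cfg.beta)
    cost = _PrefixCost(y)
    msl = cfg.min_segment

    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=np.int64)
    c1, c2 = cost.c1, cost.c2
    # Candidate last-change indices with a scheduled removal time. A tau
    # dominated at time t (F(tau) + c(tau, t) > F(t)) only becomes removable
    # once the dominating index t itself is admissible, i.e. from t + msl on;
    # removing it immediately would break exactness for min_segment > 1.
    taus = np.array([0], dtype=np.int64)
    kills = np.array([np.inf])
    for t in range(msl, n + 1):
        alive = kills > t
        if not alive.all():
            taus, kills = taus[alive], kills[alive]
        admissible = t - taus >= msl
        at = taus[admissible]
        lens = (t - at).astype(np.float64)
        s1 = c1[t] - c1[at]
        s2 = c2[t] - c2[at]
        var = s2 / lens - (s1 / lens) ** 2
        quad = np.where(var < VAR_FLOOR, var * lens / VAR_FLOOR, lens)
        var = np.maximum(var, VAR_FLOOR)
        v = F[at] + lens * np.log(var) + quad
        i_best = int(np.argmin(v))
        F[t] = v[i_best] + beta
        last[t] = at[i_best]
        dominated = v > F[t]
        if dominated.any():
            kill_mask = np.zeros(taus.size, dtype=bool)
            kill_mask[np.flatnonzero(admissible)[dominated]] = True
            kills = np.where(kill_mask & np.isinf(kills), t + msl, kills)
        if t + 1 - msl >= msl:
            taus = np.append(taus, t + 1 - msl)
            kills = np.append(kills, np.inf)
    # backtrack
    cps = []
    t = n
    while t > 0:
        tau = int(last[t])
        if tau > 0:
            cps.append(tau)
        t = tau
    cps.reverse()
    return Segmentation(change_points=tuple(cps), total_cost=float(F[n]))


def exhaustive_changepoints(
    y: np.ndarray, beta: float, min_segment: int = 2
) -> Segmentation:
    """Optimal segmentation by full O(n^2) dynamic programming, no pruning.

    Independent check for :func:`pelt_changepoints`; feasible for short
    segments only.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    cost = _PrefixCost(y)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=np.int64)
    for t in range(min_segment, n + 1):
        for tau in range(0, t - min_segment + 1):
            if tau != 0 and not (min_segment <= tau <= t - min_segment):
                continue
            if np.isinf(F[tau]):
                continue
            v = F[tau] + cost(tau, t) + beta
            if v < F[t]:
                F[t] = v
                last[t] = tau
    cps = []
    t = n
    while t > 0:
        tau = int(last[t])
        if tau > 0:
            cps.append(tau)
        t = tau
    cps.reverse()
    return Segmentation(change_points=tuple(cps), total_cost=float(F[n]))


def _segments_from_cps(cps: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    bounds = [0, *cps, n]
    return list(zip(bounds[:-1], bounds[1:]))


def pelt_events(
    trace: CurrentTrace,
    cfg: PeltConfig,
    rough: RoughConfig | None = None,
) -> EventTable:
    """Detect blockade events from PELT segmentations.

    Each candidate region (or the whole trace) is segmented; segments are
    labelled blockade when their mean lies below the midpoint of the two
    extreme segment means in that region, and consecutive blockade segments
    merge into one event. Regions that segment into a single piece yield no
    events.
    """
    if rough is None:
        regions = [(0, len(trace))]
    elif rough.mode == "global":
        regions = localize_global(trace, rough)
    else:
        regions = localize_local(trace, rough)
    events: list[tuple[int, int]] = []
    for a, b in regions:
        if b - a < 2 * cfg.min_segment:
            continue
        seg = pelt_changepoints(trace.samples[a:b], cfg)
        if not seg.change_points:
            continue
        pieces = _segments_from_cps(seg.change_points, b - a)
        means = np.array([trace.samples[a + p : a + q].mean() for p, q in pieces])
        mid = (means.min() + means.max()) / 2.0
        blockade = means < mid
        open_start: int | None = None
        for (p, q), is_block in zip(pieces, blockade):
            if is_block and open_start is None:
                open_start = a + p
            elif not is_block and open_start is not None:
                events.append((open_start, a + p))
                open_start = None
        if open_start is not None:
            events.append((open_start, a + pieces[-1][1]))
    return intervals_to_table(
        events, "pelt", trace_label=trace.label, config_digest=config_digest(cfg)
    )
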