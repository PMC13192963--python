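"""Two-sided CUSUM change detection.

An online detector for abrupt mean shifts in the current. For a segment
starting at ``k0`` it maintains the running mean ``m_k`` and variance ``v_k``
(ddof = 1) of the samples seen so far, and per-sample log-likelihood
increments for an upward and a downward shift of expected magnitude ``delta``:

    s_p[k] =  (delta / v_k) * (x[k] - m_k - delta / 2)
    s_n[k] = -(delta / v_k) * (x[k] - m_k + delta / 2)

Cumulative sums ``S_p, S_n`` and the clamped decision functions

    g_p[k] = max(g_p[k-1] + s_p[k], 0)
    g_n[k] = max(g_n[k-1] + s_n[k], 0)

confirm a change when either exceeds the threshold ``h``; the change time is
the index minimising the corresponding cumulative sum since ``k0`` (earliest
index on ties). After a confirmed change the detector restarts from the
sample after the localized change with all state zeroed, so multiple changes
per segment are found.

With ``sigma`` set in the config, ``v_k`` is replaced by ``sigma**2``
throughout; otherwise the running variance is used, floored at
``(1e-4 * delta)**2`` to keep the early samples of a segment well defined.
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

__all__ = ["CusumConfig", "cusum_changepoints", "cusum_events"]


@dataclass(frozen=True)
class CusumConfig:
    delta: float  # expected mean-shift magnitude (nA)
    h: float  # decision threshold (log-likelihood units)
    sigma: float | None = None  # fixed noise SD (nA); None -> running variance

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ConfigurationError(f"delta must be > 0, got {self.delta}")
        if self.h <= 0:
            raise ConfigurationError(f"h must be > 0, got {self.h}")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")


def cusum_changepoints(
    segment: CurrentTrace | np.ndarray, cfg: CusumConfig
) -> list[tuple[int, str]]:
    """Confirmed, localized change points of a segment.

    Returns ``(index, direction)`` pairs in increasing index order, where
    ``direction`` is ``"up"`` or ``"down"`` and ``index`` is the last sample
    of the old regime as localized by the cumulative-sum minimum.
    """
    x = segment.samples if isinstance(segment, CurrentTrace) else np.asarray(segment)
    if x.size < 2:
        raise InputError("CUSUM needs a segment of at least 2 samples")
    delta = cfg.delta
    var_fixed = None if cfg.sigma is None else cfg.sigma**2
    var_floor = (1e-4 * delta) ** 2
    floor_warned = False

    changes: list[tuple[int, str]] = []
    k0 = 0
    n = x.size
    while k0 < n - 1:
        # state for the segment starting at k0
        s1 = 0.0  # sum of x
        s2 = 0.0  # sum of x^2
        Sp = Sn = 0.0
        gp = gn = 0.0
        min_Sp = min_Sn = np.inf
        arg_Sp = arg_Sn = k0
        detected = False
        for k in range(k0, n):
            cnt = k - k0 + 1
            s1 += x[k]
            s2 += x[k] * x[k]
            mk = s1 / cnt
            if var_fixed is not None:
                vk = var_fixed
            elif cnt >= 2:
                vk = max((s2 - cnt * mk * mk) / (cnt - 1), var_floor)
            else:
                vk = var_floor
                if not floor_warned:
                    logger.warning(
                        "running variance undefined at segment start; "
                        "floored at (1e-4*delta)^2"
                    )
                    floor_warned = True
            sp = (delta / vk) * (x[k] - mk - delta / 2)
            sn = -(delta / vk) * (x[k] - mk + delta / 2)
            Sp += sp
            Sn += sn
            gp = max(gp + sp, 0.0)
            gn = max(gn + sn, 0.0)
            if Sp < min_Sp:
                min_Sp, arg_Sp = Sp, k
            if Sn < min_Sn:
                min_Sn, arg_Sn = Sn, k
            if gp > cfg.h or gn > cfg.h:
                if gp >= gn:
                    change, direction = arg_Sp, "up"
                else:
                    change, direction = arg_Sn, "down"
                changes.append((change, direction))
                k0 = change + 1
                detected = True
                break
        if not detected:
            break
    return changes


def _events_from_changes(
    changes: list[tuple[int, str]], region_start: int, region_end: int
) -> list[tuple[int, int]]:
    """Pair down changes with the next up change; trailing down closes at end."""
    events: list[tuple[int, int]] = []
    open_start: int | None = None
    for idx, direction in changes:
        if direction == "down":
            if open_start is not None:
                logger.warning(
                    "down change at %d while an event is already open at %d; "
                    "ignored",
                    region_start + idx,
                    open_start,
                )
                continue
            open_start = region_start + idx + 1  # first sample of the new level
        else:
            if open_start is None:
                continue  # up change with no open event (e.g. leading recovery)
            end = region_start + idx + 1
            if end > open_start:
                events.append((open_start, end))
            open_start = None
    if open_start is not None and region_end > open_start:
        events.append((open_start, region_end))
    return events


def cusum_events(
    trace: CurrentTrace,
    cfg: CusumConfig,
    rough: RoughConfig | None = None,
) -> EventTable:
    """Detect blockade events by pairing down/up CUSUM changes.

    When a rough-localization config is supplied, CUSUM runs only inside the
    candidate regions; otherwise it scans the whole trace.
    """
    if rough is None:
        regions = [(0, len(trace))]
    elif rough.mode == "global":
        regions = localize_global(trace, rough)
    else:
        regions = localize_local(trace, rough)
    events: list[tuple[int, int]] = []
    for a, b in regions:
        if b - a < 2:
            continue
        changes = cusum_changepoints(trace.samples[a:b], cfg)
        events.extend(_events_from_changes(changes, a, b))
    return intervals_to_table(
        events, "cusum", trace_label=trace.label, config_digest=config_digest(cfg)
    )
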