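"""Cluster-based event detection (CBED) with a fixed global threshold.

The current histogram of a trace is modelled as a two-component Gaussian
mixture

    p(I) = pi0 * N(I | mu0, s0^2) + pi1 * N(I | mu1, s1^2),

approximated by two-means clustering of the one-dimensional samples: the
cluster centroids serve as the component means, and each component's weight
and variance come from its hard cluster assignment. The larger-weight
component is the open-pore (baseline) cluster.

The *vertical* (amplitude) threshold is the current at which the two weighted
component densities are equal — the valley of the mixture — obtained as the
root of a quadratic in closed form. The *horizontal* (duration) threshold
converts a minimum event duration ``tau_min`` into ``Nmin = ceil(tau_min *
fs)`` consecutive samples. An event is a contiguous run of samples strictly
beyond the vertical threshold whose length is at least ``Nmin``; both
conditions are enforced jointly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import (
    ConfigurationError,
    CurrentTrace,
    DegenerateFitError,
    EventTable,
    InputError,
    ThresholdFallbackError,
    config_digest,
    intervals_to_table,
    runs_from_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureFit",
    "CbedConfig",
    "fit_mixture",
    "vertical_threshold",
    "cbed_events",
    "mixture_histogram",
]

_LLOYD_TOL = 1e-10  # nA; centroid movement below this stops Lloyd iterations


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture of the current histogram.

    Component 0 is the baseline (open-pore) cluster: the larger-weight
    component, ties broken toward the higher (less blocked) mean.
    """

    pi0: float
    pi1: float
    mu0: float
    mu1: float
    var0: float
    var1: float

    def __post_init__(self) -> None:
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-12:
            raise ConfigurationError("mixture weights must sum to 1")
        if min(self.pi0, self.pi1) < 0:
            raise ConfigurationError("mixture weights must be non-negative")
        if min(self.var0, self.var1) <= 0:
            raise ConfigurationError("component variances must be positive")

    def density(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.pi0 * _normal_pdf(x, self.mu0, self.var0) + self.pi1 * _normal_pdf(
            x, self.mu1, self.var1
        )

    def component_balance(self, x: float) -> float:
        """Signed difference of the weighted component densities at ``x``."""
        return self.pi0 * _normal_pdf(x, self.mu0, self.var0) - self.pi1 * _normal_pdf(
            x, self.mu1, self.var1
        )


def _normal_pdf(x, mu, var):
    return np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)


@dataclass(frozen=True)
class CbedConfig:
    tau_min: float = 1e-3  # minimum event duration (s)
    polarity: Literal["down", "up"] = "down"
    histogram_bins: int = 100  # diagnostics only

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ConfigurationError(f"tau_min must be > 0, got {self.tau_min}")
        if self.polarity not in ("down", "up"):
            raise ConfigurationError(f"polarity must be 'down' or 'up'")
        if self.histogram_bins < 10:
            raise ConfigurationError("histogram_bins must be >= 10")


def fit_mixture(trace: CurrentTrace) -> MixtureFit:
    """Fit the two-component mixture by deterministic two-means clustering.

    Lloyd's algorithm on the 1-D current values, centroids initialised at the
    10th and 90th percentiles, iterated until the centroids move less than
    1e-10 nA. Weights and variances come from the hard assignments
    (variance ddof = 1), so clusters of fewer than 2 samples are degenerate.
    """
    x = np.asarray(trace.samples, dtype=np.float64)
    if x.size < 10:
        raise InputError("mixture fit needs at least 10 samples")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError(
            "all samples identical; no mixture structure — consider the "
            "adaptive detector"
        )
    c_lo, c_hi = np.percentile(x, [10.0, 90.0])
    if c_lo == c_hi:  # heavy ties; fall back to extremes
        c_lo, c_hi = float(x.min()), float(x.max())
    # 1-D two-means: assignment is a threshold at the centroid midpoint
    for _ in range(1000):
        mid = (c_lo + c_hi) / 2.0
        lo_mask = x <= mid
        if not lo_mask.any() or lo_mask.all():
            raise DegenerateFitError(
                "a cluster is empty; the trace is effectively unimodal — "
                "consider the adaptive detector"
            )
        new_lo, new_hi = x[lo_mask].mean(), x[~lo_mask].mean()
        moved = max(abs(new_lo - c_lo), abs(new_hi - c_hi))
        c_lo, c_hi = float(new_lo), float(new_hi)
        if moved < _LLOYD_TOL:
            break
    mid = (c_lo + c_hi) / 2.0
    lo_mask = x <= mid
    n_lo, n_hi = int(lo_mask.sum()), int((~lo_mask).sum())
    if min(n_lo, n_hi) < 2:
        raise DegenerateFitError(
            f"cluster with {min(n_lo, n_hi)} member(s) cannot carry a "
            "variance — consider the adaptive detector"
        )
    w_lo, w_hi = n_lo / x.size, n_hi / x.size
    var_lo = float(np.var(x[lo_mask], ddof=1))
    var_hi = float(np.var(x[~lo_mask], ddof=1))
    # perfectly two-level traces have zero within-cluster spread; a floor far
    # below the centroid separation keeps the valley solvable (at ~midpoint)
    var_floor = (1e-9 * (c_hi - c_lo)) ** 2
    if min(var_lo, var_hi) < var_floor:
        logger.warning("near-zero within-cluster variance floored at %g", var_floor)
        var_lo = max(var_lo, var_floor)
        var_hi = max(var_hi, var_floor)
    # baseline = larger weight; tie -> higher mean
    if (w_hi > w_lo) or (w_hi == w_lo):
        return MixtureFit(w_hi, w_lo, c_hi, c_lo, var_hi, var_lo)
    return MixtureFit(w_lo, w_hi, c_lo, c_hi, var_lo, var_hi)


def vertical_threshold(fit: MixtureFit) -> float:
    """The valley of the mixture: the root of the density-equality condition.

    Equating the two weighted component densities and taking logs gives a
    quadratic

        A e^2 + B e + C = 0
        A = 1/(2 var1) - 1/(2 var0)
        B = mu0/var0 - mu1/var1
        C = mu1^2/(2 var1) - mu0^2/(2 var0) + ln(pi0 sd1 / (pi1 sd0))

    whose root strictly between the component means is returned. Equal
    variances make the equation linear; it is solved directly.
    """
    p0, p1 = fit.pi0, fit.pi1
    m0, m1 = fit.mu0, fit.mu1
    v0, v1 = fit.var0, fit.var1
    if p1 == 0.0:
        raise ThresholdFallbackError("event component has zero weight")
    lo, hi = min(m0, m1), max(m0, m1)
    if lo == hi:
        raise ThresholdFallbackError("component means coincide; no valley exists")
    A = 1.0 / (2 * v1) - 1.0 / (2 * v0)
    B = m0 / v0 - m1 / v1
    C = (
        m1**2 / (2 * v1)
        - m0**2 / (2 * v0)
        + math.log(p0 / p1)
        + 0.5 * math.log(v1 / v0)
    )
    if A == 0.0:
        if B == 0.0:
            raise ThresholdFallbackError("degenerate linear equation for the valley")
        roots = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            raise ThresholdFallbackError(
                "no real density-equality point — consider the adaptive detector"
            )
        sq = math.sqrt(disc)
        roots = [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
    inside = [r for r in roots if lo < r < hi]
    if not inside:
        raise ThresholdFallbackError(
            "no density-equality root between the component means — "
            "consider the adaptive detector"
        )
    return float(inside[0] if len(inside) == 1 else min(inside, key=lambda r: abs(r - (lo + hi) / 2)))


def n_min_samples(tau_min: float, fs: float) -> int:
    """Horizontal threshold: minimum duration in samples, ``ceil(tau_min * fs)``."""
    return max(1, math.ceil(tau_min * fs))


def cbed_events(
    trace: CurrentTrace, cfg: CbedConfig = CbedConfig()
) -> tuple[EventTable, MixtureFit, float]:
    """Detect events with the fixed (global) CBED threshold.

    Returns the event table, the mixture fit, and the vertical threshold.
    An event is any maximal run of samples strictly below the threshold
    (above, for ``polarity="up"``) lasting at least ``ceil(tau_min * fs)``
    samples.
    """
    work = trace if cfg.polarity == "down" else trace.flipped()
    fit = fit_mixture(work)
    thresh = vertical_threshold(fit)
    nmin = n_min_samples(cfg.tau_min, trace.fs)
    mask = work.samples < thresh
    runs = [(a, b) for a, b in runs_from_mask(mask) if b - a >= nmin]
    table = intervals_to_table(
        runs, "cbed", trace_label=trace.label, config_digest=config_digest(cfg)
    )
    return table, fit, thresh if cfg.polarity == "down" else -thresh


def mixture_histogram(
    trace: CurrentTrace, fit: MixtureFit, bins: int = 100
) -> np.ndarray:
    """Diagnostic table (bin_center, count, density0, density1) for plotting."""
    counts, edges = np.histogram(trace.samples, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    d0 = fit.pi0 * _normal_pdf(centers, fit.mu0, fit.var0)
    d1 = fit.pi1 * _normal_pdf(centers, fit.mu1, fit.var1)
    return np.column_stack([centers, counts, d0, d1])
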