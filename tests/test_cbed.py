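"""CBED: mixture fit, valley threshold, joint amplitude/duration calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porecall import (
    CbedConfig,
    CurrentTrace,
    DegenerateFitError,
    MixtureFit,
    SyntheticSpec,
    ThresholdFallbackError,
    cbed_events,
    fit_mixture,
    generate,
    match_events,
    random_event_train,
    vertical_threshold,
)
from porecall.cbed import n_min_samples


def grid_valley(fit: MixtureFit, resolution: float = 1e-6) -> float:
    """Independent oracle: dense-grid search for the density-equality point."""
    lo, hi = sorted([fit.mu0, fit.mu1])
    grid = np.arange(lo + resolution, hi, resolution)
    balance = np.abs(
        fit.pi0 * np.exp(-((grid - fit.mu0) ** 2) / (2 * fit.var0)) / np.sqrt(fit.var0)
        - fit.pi1 * np.exp(-((grid - fit.mu1) ** 2) / (2 * fit.var1)) / np.sqrt(fit.var1)
    )
    return float(grid[np.argmin(balance)])


class TestFitMixture:
    def test_bimodal_trace_recovers_weights_and_means(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [1.0 + 0.01 * rng.normal(size=900), 0.6 + 0.01 * rng.normal(size=100)]
        )
        fit = fit_mixture(CurrentTrace(x, fs=1.0))
        assert fit.pi0 == pytest.approx(0.9, abs=0.02)
        assert fit.mu0 == pytest.approx(1.0, abs=0.02)
        assert fit.mu1 == pytest.approx(0.6, abs=0.02)
        assert fit.pi0 + fit.pi1 == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_tie_breaks_to_higher_mean(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [0.0 + 0.01 * rng.normal(size=500), 1.0 + 0.01 * rng.normal(size=500)]
        )
        fit = fit_mixture(CurrentTrace(x, fs=1.0))
        assert fit.pi0 == pytest.approx(0.5, abs=0.01)
        assert fit.mu0 > fit.mu1  # baseline is the higher-mean component

    def test_single_valued_trace_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_mixture(CurrentTrace(np.full(100, 1.0), fs=1.0))

    def test_tiny_cluster_degenerate(self):
        x = np.concatenate([np.full(99, 1.0) + np.arange(99) * 1e-6, [0.0]])
        with pytest.raises(DegenerateFitError):
            fit_mixture(CurrentTrace(x, fs=1.0))


class TestVerticalThreshold:
    def test_equal_weight_equal_variance_is_midpoint(self):
        fit = MixtureFit(0.5, 0.5, 1.0, 0.6, 0.0025, 0.0025)
        assert vertical_threshold(fit) == pytest.approx(0.8, abs=1e-15)

    def test_unequal_weights_shift_toward_rare_component(self):
        fit = MixtureFit(0.9, 0.1, 1.0, 0.6, 0.0025, 0.0025)
        thr = vertical_threshold(fit)
        assert thr < 0.8
        assert thr == pytest.approx(grid_valley(fit), abs=2e-6)

    def test_unequal_variances_root_satisfies_density_equality(self):
        fit = MixtureFit(0.5, 0.5, 1.0, 0.6, 0.02**2, 0.10**2)
        thr = vertical_threshold(fit)
        assert 0.6 < thr < 1.0
        assert abs(fit.component_balance(thr)) < 1e-9

    def test_no_interior_root_raises(self):
        # an overwhelming baseline with huge variance has no valley between
        # the means: the event density never exceeds the baseline's there
        fit = MixtureFit(1.0 - 1e-9, 1e-9, 1.0, 0.9, 0.5, 1e-6)
        with pytest.raises(ThresholdFallbackError):
            vertical_threshold(fit)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_valley_contract_on_random_mixtures(self, seed):
        """Threshold lies strictly between the means with ~zero residual."""
        rng = np.random.default_rng(seed)
        pi0 = rng.uniform(0.5, 0.99)
        mu1 = rng.uniform(0.2, 0.8)
        sd0 = rng.uniform(0.01, 0.08)
        sd1 = rng.uniform(0.01, 0.08)
        pooled = np.sqrt((sd0**2 + sd1**2) / 2)
        mu0 = mu1 + rng.uniform(1.0, 10.0) * pooled
        fit = MixtureFit(pi0, 1 - pi0, mu0, mu1, sd0**2, sd1**2)
        try:
            thr = vertical_threshold(fit)
        except ThresholdFallbackError:
            return  # legitimate: no valley between the means
        assert mu1 < thr < mu0
        assert abs(fit.component_balance(thr)) < 1e-9


class TestCbedEvents:
    def test_nmin_arithmetic(self):
        assert n_min_samples(1e-3, 1e6) == 1000
        assert n_min_samples(1e-3, 999_999.0) == 1000  # ceiling

    def test_high_contrast_recovery(self, high_contrast_trace):
        trace, truth = high_contrast_trace
        table, fit, thr = cbed_events(trace, CbedConfig(tau_min=1e-3))
        assert len(table) == len(truth) == 20
        tp, fp, fn = match_events(truth, table, 0.8)
        assert (tp, fp, fn) == (20, 0, 0)
        assert fit.mu1 < thr < fit.mu0

    def test_sub_tau_min_spike_rejected(self):
        events = random_event_train(10, 1.0, 5e-3, 0.4, seed=9, guard_s=10e-3)
        # inject a 0.3 ms spike well away from real events
        spike = (0.9985, 0.3e-3, 0.4)
        spec = SyntheticSpec(
            fs=100_000.0, duration_s=1.0, baseline=1.0, noise_sd=0.02,
            events=sorted(events + [spike]), seed=10,
        )
        trace, _ = generate(spec)
        table, _, _ = cbed_events(trace, CbedConfig(tau_min=1e-3))
        assert len(table) == 10
        spike_start = int(round(0.9985 * 100_000))
        for ev in table:
            assert ev.end <= spike_start or ev.start >= spike_start + 30

    def test_event_definition_conjunction(self, high_contrast_trace):
        trace, _ = high_contrast_trace
        cfg = CbedConfig(tau_min=1e-3)
        table, _, thr = cbed_events(trace, cfg)
        nmin = n_min_samples(cfg.tau_min, trace.fs)
        for ev in table:
            assert ev.dwell_samples >= nmin
            assert np.all(trace.samples[ev.start : ev.end] < thr)

    def test_event_count_non_increasing_in_tau_min(self, high_contrast_trace):
        trace, _ = high_contrast_trace
        counts = [
            len(cbed_events(trace, CbedConfig(tau_min=t))[0])
            for t in (1e-4, 1e-3, 3e-3, 6e-3, 2e-2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_noiseless_two_level_exact_recovery(self):
        spec = SyntheticSpec(
            fs=10_000.0, duration_s=0.5, baseline=1.0, noise_sd=0.0,
            events=[(0.1, 0.02, 0.4), (0.3, 0.05, 0.4)], seed=0,
        )
        trace, truth = generate(spec)
        table, _, _ = cbed_events(trace, CbedConfig(tau_min=1e-3))
        assert [(e.start, e.end) for e in table] == [
            (e.start, e.end) for e in truth
        ]

    def test_polarity_up(self):
        spec = SyntheticSpec(
            fs=10_000.0, duration_s=0.5, baseline=1.0, noise_sd=0.02,
            events=[(0.2, 0.05, 0.4)], seed=15,
        )
        trace, truth = generate(spec)
        upside = CurrentTrace(-trace.samples, fs=trace.fs)
        table, _, _ = cbed_events(upside, CbedConfig(tau_min=1e-3, polarity="up"))
        assert len(table) == 1
        assert abs(table.events[0].start - truth.events[0].start) <= 2
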