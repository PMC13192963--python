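"""Feature extraction (dwell, height, mean) and K-means clustering."""

import numpy as np
import pytest

from porecall import (
    ConsistencyError,
    CurrentTrace,
    EventInterval,
    EventTable,
    InputError,
    SyntheticSpec,
    extract_features,
    feature_table,
    generate,
    kmeans_features,
    pre_event_baseline,
    random_event_train,
)


def _rect_trace(baseline=1.0, level=0.6, n_pre=200, n_event=500, fs=100_000.0):
    x = np.full(n_pre + n_event + n_pre, baseline)
    x[n_pre : n_pre + n_event] = level
    return CurrentTrace(x, fs=fs), EventInterval(n_pre, n_pre + n_event, "cbed")


class TestExtractFeatures:
    def test_rectangular_event_exact(self):
        trace, ev = _rect_trace()  # 5 ms at 100 kHz, depth 0.4
        f = extract_features(trace, ev, baseline_ref=1.0)
        assert f.dwell_s == pytest.approx(0.005)
        assert f.height_nA == pytest.approx(0.4)
        assert f.mean_nA == pytest.approx(-0.4)

    def test_triangular_dip_mean_is_half_height(self):
        # symmetric V: drop ramps 0 -> 0.5 -> 0 linearly
        n = 201
        drop = 0.5 * (1 - np.abs(np.linspace(-1, 1, n)))
        x = 1.0 - drop
        trace = CurrentTrace(x, fs=1000.0)
        f = extract_features(trace, EventInterval(0, n, "cbed"), baseline_ref=1.0)
        assert f.height_nA == pytest.approx(0.5)
        assert f.mean_nA == pytest.approx(-0.25, abs=2e-3)  # discrete ramp

    def test_zero_depth_event_degenerate_equality(self):
        trace = CurrentTrace(np.full(100, 1.0), fs=1000.0)
        f = extract_features(trace, EventInterval(10, 20, "cbed"), baseline_ref=1.0)
        assert f.height_nA == 0.0
        assert f.mean_nA == 0.0

    def test_mean_never_exceeds_height(self):
        rng = np.random.default_rng(4)
        trace = CurrentTrace(1.0 + 0.1 * rng.normal(size=1000), fs=1000.0)
        for start in range(0, 900, 97):
            f = extract_features(
                trace, EventInterval(start, start + 50, "cbed"), baseline_ref=1.0
            )
            assert abs(f.mean_nA) <= f.height_nA + 1e-12

    def test_series_baseline_reference(self):
        trace, ev = _rect_trace()
        baseline = np.full(len(trace), 1.0)
        f = extract_features(trace, ev, baseline_ref=baseline)
        assert f.height_nA == pytest.approx(0.4)

    def test_short_baseline_series_rejected(self):
        trace, ev = _rect_trace()
        with pytest.raises(ConsistencyError):
            extract_features(trace, ev, baseline_ref=np.ones(10))


class TestFeatureTable:
    def test_three_rectangular_events_exact_rows(self):
        spec = SyntheticSpec(
            fs=10_000.0, duration_s=1.0, baseline=1.0, noise_sd=0.0,
            events=[(0.1, 0.02, 0.2), (0.4, 0.03, 0.3), (0.7, 0.04, 0.4)], seed=0,
        )
        trace, truth = generate(spec)
        df = feature_table(trace, truth, baseline_ref=1.0)
        assert list(df["dwell_s"]) == pytest.approx([0.02, 0.03, 0.04])
        assert list(df["height_nA"]) == pytest.approx([0.2, 0.3, 0.4])
        assert list(df["mean_nA"]) == pytest.approx([-0.2, -0.3, -0.4])

    def test_empty_table_gives_header_only_frame(self):
        trace = CurrentTrace(np.ones(100), fs=1000.0)
        df = feature_table(trace, EventTable([]), baseline_ref=1.0)
        assert len(df) == 0
        assert list(df.columns) == ["event_id", "dwell_s", "height_nA", "mean_nA"]

    def test_mismatched_trace_rejected(self):
        trace = CurrentTrace(np.ones(100), fs=1000.0)
        table = EventTable([EventInterval(50, 150, "cbed")])
        with pytest.raises(ConsistencyError):
            feature_table(trace, table, baseline_ref=1.0)

    def test_pre_event_baseline_uses_clean_context(self):
        spec = SyntheticSpec(
            fs=10_000.0, duration_s=1.0, baseline=1.0, noise_sd=0.0,
            events=[(0.1, 0.02, 0.2), (0.102 + 0.02, 0.02, 0.3)], seed=0,
        )
        trace, truth = generate(spec)
        refs = pre_event_baseline(trace, truth)
        assert refs == pytest.approx([1.0, 1.0])


class TestKmeans:
    def _two_population_features(self):
        # 50 events of depth 0.2 nA then 50 of depth 0.4 nA, in time order
        events = random_event_train(
            100, 2.0, 5e-3, 0.2, seed=31, guard_s=2e-3
        )
        depths = [0.2] * 50 + [0.4] * 50
        events = [(o, d, depth) for (o, d, _), depth in zip(events, depths)]
        spec = SyntheticSpec(
            fs=50_000.0, duration_s=2.0, baseline=1.0, noise_sd=0.01,
            events=events, seed=32,
        )
        trace, truth = generate(spec)
        df = feature_table(trace, truth, baseline_ref=1.0)
        return df, np.array([0] * 50 + [1] * 50)

    def test_two_separated_populations_recovered(self):
        df, true_labels = self._two_population_features()
        res = kmeans_features(df, k=2, seed=0)
        # perfect recovery up to label permutation
        agree = np.mean(res.assignments == true_labels)
        assert max(agree, 1 - agree) == 1.0

    def test_k1_centroid_is_coordinate_mean(self):
        df, _ = self._two_population_features()
        res = kmeans_features(df, k=1, seed=0)
        pts = df[["mean_nA", "height_nA"]].to_numpy()
        assert np.allclose(res.centroids[0], pts.mean(axis=0))

    def test_inertia_beats_random_assignment(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 1, size=(40, 2))
        import pandas as pd

        df = pd.DataFrame(pts, columns=["mean_nA", "height_nA"])
        df.insert(0, "event_id", range(40))
        df.insert(1, "dwell_s", 0.01)
        res = kmeans_features(df, k=2, seed=1)
        for _ in range(20):
            labels = rng.integers(0, 2, 40)
            if len(np.unique(labels)) < 2:
                continue
            cents = np.vstack([pts[labels == j].mean(axis=0) for j in range(2)])
            inertia = ((pts - cents[labels]) ** 2).sum()
            assert res.inertia <= inertia + 1e-9

    def test_fewer_events_than_k_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"event_id": [0], "dwell_s": [0.01], "height_nA": [0.4], "mean_nA": [-0.4]}
        )
        with pytest.raises(InputError):
            kmeans_features(df, k=2, seed=0)

    def test_deterministic_given_seed(self):
        df, _ = self._two_population_features()
        a = kmeans_features(df, k=2, seed=5)
        b = kmeans_features(df, k=2, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
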