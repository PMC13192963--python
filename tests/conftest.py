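import numpy as np
import pytest

from porecall import CurrentTrace, Drift, SyntheticSpec, generate, random_event_train


@pytest.fixture
def step_trace() -> CurrentTrace:
    """Noiseless two-level step: 500 samples at 1.0 nA, then 500 at 0.6 nA."""
    x = np.concatenate([np.full(500, 1.0), np.full(500, 0.6)])
    return CurrentTrace(x, fs=1000.0, label="step")


@pytest.fixture
def clean_event_trace():
    """One rectangular 0.4 nA event on a 1.0 nA baseline with mild noise."""
    spec = SyntheticSpec(
        fs=10_000.0,
        duration_s=0.5,
        baseline=1.0,
        noise_sd=0.01,
        events=[(0.2, 0.02, 0.4)],
        seed=11,
    )
    return generate(spec)


@pytest.fixture
def high_contrast_trace():
    """Twenty well-separated events, depth/noise ratio 20."""
    events = random_event_train(
        20, 1.0, (3e-3, 6e-3), 0.4, seed=7, guard_s=5e-3
    )
    spec = SyntheticSpec(
        fs=100_000.0,
        duration_s=1.0,
        baseline=1.0,
        noise_sd=0.02,
        events=events,
        seed=3,
    )
    return generate(spec)


@pytest.fixture
def drifting_trace():
    """Events of depth 0.3 nA under a linear drift of -1.5 nA over 1 s."""
    events = random_event_train(
        20, 1.0, (3e-3, 6e-3), 0.3, seed=8, guard_s=5e-3
    )
    spec = SyntheticSpec(
        fs=100_000.0,
        duration_s=1.0,
        baseline=1.0,
        noise_sd=0.02,
        events=events,
        drift=Drift("linear", slope=-1.5),
        seed=4,
    )
    return generate(spec)
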