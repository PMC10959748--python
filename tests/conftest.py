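import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_bundle(rng):
    """Small fully populated session bundle (3 trials, 4 units)."""
    from socoop.synth import simulate_neural_session, default_units
    bundle, _ = simulate_neural_session(
        1, rng, n_trials=3, units=default_units(2, 2))
    return bundle
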