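import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_config():
    """Small single-trial study used across integration tests."""
    from rhythmarousal import SynthConfig

    return SynthConfig(seed=7, n_trials=1, trial_on_s=600.0, trial_off_s=0.0,
                       motion_rate_per_min=0.0)
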