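import pytest
from hypothesis import HealthCheck, settings

from crossmodal import ModelParams, base_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def spatial_cfg():
    """Synchronous stimuli, onset 0.2 s, duration 0.3 s, default geometry."""
    return base_config(7.0)
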