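import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fdpsim import ModelParams, SimulationConfig


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def source_params() -> ModelParams:
    """Source-model learning-rate variant (p2 = p1 × 1e-4)."""
    return ModelParams(p2=1e-5)


@pytest.fixture(scope="session")
def short_cfg() -> SimulationConfig:
    """2-second protocol for fast integrator tests."""
    return SimulationConfig(duration=2000.0, window_start=1000.0,
                            window_end=2000.0, trace_stride=1)
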