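import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aidsim.pig import REFERENCE_PIGS, SensorModel

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def noiseless_sensor() -> SensorModel:
    return SensorModel(noise_sd=0.0, bias=0.0)


@pytest.fixture
def herd():
    return REFERENCE_PIGS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
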