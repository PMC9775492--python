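import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plant_config():
    from valveflow.pneumatics import default_plant_config
    return default_plant_config()


@pytest.fixture
def glucose_chip():
    from valveflow.chip import build_glucose_chip
    return build_glucose_chip()


@pytest.fixture
def separation_chip():
    from valveflow.chip import build_separation_chip
    return build_separation_chip()
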