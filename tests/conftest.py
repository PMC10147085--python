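import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from tracerank import (
    calibrate_preference_config,
    crispify,
    load_fixture,
)


@pytest.fixture(scope="session")
def fixture():
    return load_fixture()


@pytest.fixture(scope="session")
def crisp(fixture):
    return crispify(fixture.matrix, fixture.scale)


@pytest.fixture(scope="session")
def calibration(fixture):
    """Calibrated replication configuration (deterministic, reused)."""
    return calibrate_preference_config(fixture)
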