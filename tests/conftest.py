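import numpy as np
import pytest

from hexachrome import SensorConfig, build_default_qe


@pytest.fixture(scope="session")
def qe():
    return build_default_qe()


@pytest.fixture(scope="session")
def config():
    return SensorConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Sensor with read noise disabled (shot noise only)."""
    return SensorConfig(read_noise=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
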