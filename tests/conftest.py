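import numpy as np
import pytest

from svdcvr import SimulationConfig, build_paradigm, resample_etco2, simulate_etco2


@pytest.fixture(scope="session")
def schedule():
    """Standard 12-minute 2-3-2-3-2 challenge at TR = 1.55 s."""
    return build_paradigm((2, 3, 2, 3, 2), 1.55)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def regressor(schedule, default_config):
    """Noise-free EtCO2 regressor on the volume grid."""
    trace = simulate_etco2(default_config)
    return resample_etco2(trace, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
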