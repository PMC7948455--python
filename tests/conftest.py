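import numpy as np
import pytest

from fltscreen import InstrumentResponse, SimConfig


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=123)


@pytest.fixture(scope="session")
def irf(sim_config: SimConfig) -> InstrumentResponse:
    return InstrumentResponse.gaussian(sim_config.irf_center, sim_config.irf_width_sigma)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
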