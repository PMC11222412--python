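import numpy as np
import pytest

from srstroke.synthetic_data import SimulationConfig, generate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_patient(noiseless_config):
    return generate_patient(noiseless_config, label=1,
                            rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def noisy_patient():
    cfg = SimulationConfig(seed=11)
    return generate_patient(cfg, label=0, rng=np.random.default_rng(11))
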