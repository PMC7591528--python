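import numpy as np
import pytest

from ptjplfuse.ptjpl import default_biome_params
from ptjplfuse.synth import SynthConfig, generate_forcing, generate_observations


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def forcing(synth_config):
    return generate_forcing(synth_config)


@pytest.fixture(scope="session")
def observations(synth_config, forcing):
    return generate_observations(synth_config, forcing)


@pytest.fixture(scope="session")
def biome_lut():
    return default_biome_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
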