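import numpy as np
import pytest

from remap_rsa import SimConfig, StimulusCatalog, generate_dataset


@pytest.fixture(scope="session")
def catalog():
    return StimulusCatalog.default(18)


@pytest.fixture(scope="session")
def small_catalog():
    return StimulusCatalog.default(4)


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(n_participants=3, n_pairmates=6, n_voxels=24, seed=7,
                     regions={"HC": "remap", "HC2": "stable", "V1": "sensory"})


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
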