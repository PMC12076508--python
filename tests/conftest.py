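import numpy as np
import pytest

from ohecc import GeneratorConfig, make_dataset


@pytest.fixture(scope="session")
def mixed_dataset():
    """Small mixed dataset: 150 molecules, 30 per center count 0-4."""
    return make_dataset(GeneratorConfig(n_molecules=150, seed=11))


@pytest.fixture(scope="session")
def single_center_config():
    return GeneratorConfig(center_distribution={1: 1.0}, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
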