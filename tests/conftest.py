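import numpy as np
import pytest

from sonarcount.synthetic import GeneratorConfig, desk_scale_config, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_config():
    return desk_scale_config()


@pytest.fixture(scope="session")
def small_dataset():
    """20 desk-scale frames with annotations, shared across tests."""
    images, manifest = generate_dataset(20, desk_scale_config(), seed=7)
    return images, manifest


@pytest.fixture(scope="session")
def full_frame_config():
    return GeneratorConfig()
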