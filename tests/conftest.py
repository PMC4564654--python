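import numpy as np
import pytest
from hypothesis import settings

import tonalnet as tn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def major_profile():
    return tn.default_profile(tn.Mode.MAJOR)


@pytest.fixture(scope="session")
def minor_profile():
    return tn.default_profile(tn.Mode.MINOR)


@pytest.fixture(scope="session")
def tiny_augmented_corpus():
    """24 items: one C-major and one A-minor base melody, all transpositions."""
    rng = np.random.default_rng(7)
    m1 = tn.generate_melody(
        tn.KeyLabel(0, tn.Mode.MAJOR), 17, tn.default_profile(tn.Mode.MAJOR), rng
    )
    m2 = tn.generate_melody(
        tn.KeyLabel(9, tn.Mode.MINOR), 17, tn.default_profile(tn.Mode.MINOR), rng
    )
    return tn.augment_by_transposition(tn.Corpus([m1, m2]))


@pytest.fixture(scope="session")
def mini_state():
    """A miniature network instance (20 inputs) for gradient work."""
    from tonalnet.network import init_network

    return init_network(3, layer_sizes=(20, 6, 5, 24))
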