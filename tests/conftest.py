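import numpy as np
import pytest

import embfilter as ef


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A small but non-trivial architecture for fast tests."""
    return ef.ModelConfig(embed_dim=8, n_blocks=2, kernel_size=3)


@pytest.fixture
def small_params(small_cfg):
    return ef.init_params(small_cfg, np.random.default_rng(0))


def random_protein(rng, length):
    return "".join(rng.choice(list(ef.model.AMINO_ACIDS), size=length))


@pytest.fixture
def random_protein_factory(rng):
    return lambda length: random_protein(rng, length)
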