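import numpy as np
import pytest

from braggfxs.synthetic import make_toy_crystal, published_test_cells


@pytest.fixture(scope="session")
def bundle():
    """Default desk-scale triclinic toy bundle (n_q=32, n_θ=32, n_η=128)."""
    return make_toy_crystal(seed=11)


@pytest.fixture(scope="session")
def cells():
    return published_test_cells()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
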