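import numpy as np
import pytest

from nichetropism import datasets
from nichetropism.phylosignal import load_tree


@pytest.fixture(scope="session")
def wolbachia_tree():
    return datasets.load_wolbachia_tree()


@pytest.fixture(scope="session")
def wolbachia_states():
    return datasets.wolbachia_character()


@pytest.fixture(scope="session")
def drosophila_tree():
    return datasets.load_drosophila_tree()


@pytest.fixture(scope="session")
def drosophila_states():
    return datasets.drosophila_character()


@pytest.fixture
def balanced8_tree():
    """Balanced 8-tip tree with a clean root split."""
    return load_tree("(((A,B),(C,D)),((E,F),(G,H)));")


@pytest.fixture
def quartet_tree():
    return load_tree("((A,B),(C,D));")


@pytest.fixture
def uniform_stack():
    """Tiny stack with hand-set intensities for exact density checks."""
    from nichetropism.image_quant import ImageStack

    wolb = np.zeros((4, 8, 8))
    wolb[:, :4, :] = 6.0  # hub half
    wolb[:, 4:, :] = 2.0  # surround half
    return ImageStack(channels={"wolbachia": wolb})


@pytest.fixture
def half_masks():
    from nichetropism.image_quant import MaskSet

    hub = np.zeros((4, 8, 8), dtype=bool)
    surround = np.zeros((4, 8, 8), dtype=bool)
    hub[:, :4, :] = True
    surround[:, 4:, :] = True
    return MaskSet(hub=hub, surround=surround)
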