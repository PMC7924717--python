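import numpy as np
import pytest

from markermol.fixtures import (generate_fixture, toy_helix, zigzag_chain,
                                hexaglycine_linker)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def lys_glu():
    pair = generate_fixture("lys_glu_pair")
    return pair["lysine"], pair["glutamate"]


@pytest.fixture
def helix10():
    return toy_helix(10, seed=1)


@pytest.fixture
def butane_like():
    return zigzag_chain(4, 1.5)


@pytest.fixture
def hexagly():
    return hexaglycine_linker()


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
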