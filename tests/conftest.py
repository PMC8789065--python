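import numpy as np
import pytest

from evoscape.alphabet import Alphabet
from evoscape.landscape import PottsModel
from evoscape.validation import integration_landscape


@pytest.fixture(scope="session")
def toy_abc():
    return Alphabet("ABC", gap=None)


@pytest.fixture(scope="session")
def toy2_model(toy_abc):
    """L=2, 3-state model: h_0(B)=1, J_01(B,C)=0.5, all else 0."""
    h = np.zeros((2, 3))
    h[0, 1] = 1.0
    J = np.zeros((2, 2, 3, 3))
    J[0, 1, 1, 2] = 0.5
    J[1, 0, 2, 1] = 0.5
    return PottsModel(h, J, toy_abc)


def make_random_model(seed, L=5, q=4):
    rng = np.random.default_rng(seed)
    alphabet = Alphabet("ABCDEFGH"[:q], gap=None)
    h = rng.normal(size=(L, q))
    J = rng.normal(size=(L, L, q, q))
    J = 0.5 * (J + np.transpose(J, (1, 0, 3, 2)))
    J[np.arange(L), np.arange(L)] = 0.0
    return PottsModel(h, J, alphabet)


@pytest.fixture(scope="session")
def planted():
    """Session-wide 21-state planted-contact landscape with wildtype."""
    model, cmap, wt = integration_landscape(1)
    return model, cmap, wt
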