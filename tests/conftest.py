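import numpy as np
import pytest

from ensdesign.fixtures import FixtureSpec, make_random_potts, make_toy_backbone
from ensdesign.potts import SequenceState


def loop_energy(model, seq):
    """Independent term-by-term energy oracle."""
    e = 0.0
    s = seq.residues
    for i in range(model.L):
        e += model.h[i, s[i]]
    for (i, j), block in model.couplings.items():
        e += block[s[i], s[j]]
    return e


def random_seq(model, rng):
    return SequenceState(rng.integers(0, model.A, size=model.L), model.alphabet)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model():
    return make_random_potts(5, 4, edge_density=0.6, seed=42)


@pytest.fixture
def helix20():
    return make_toy_backbone(FixtureSpec("helix", 20, 0))
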