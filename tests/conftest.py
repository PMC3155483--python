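import numpy as np
import pytest

from symdyn import Alphabet, SymbolSequence
from symdyn.datasets import synthetic_session

BINARY = Alphabet(("0", "1"))


@pytest.fixture
def binary_alphabet():
    return BINARY


@pytest.fixture
def constant_seq():
    return SymbolSequence(("1",) * 1000, BINARY)


@pytest.fixture
def random_binary_seq():
    rng = np.random.default_rng(42)
    return SymbolSequence(tuple(str(b) for b in rng.integers(0, 2, 1000)), BINARY)


@pytest.fixture
def session():
    """Synthetic coded session at the scale of the study's first session."""
    return synthetic_session(length=317, seed=17, duration_minutes=60.0)


def make_seq(text, alphabet=None):
    return SymbolSequence(tuple(text), alphabet)
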