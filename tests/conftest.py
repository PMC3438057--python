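import numpy as np
import pytest

from deltapssm.matrices import Alphabet, default_matrix


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length, background=None):
    if background is None:
        background = np.full(20, 0.05)
    idx = rng.choice(20, size=length, p=background)
    return "".join(Alphabet.RESIDUES[i] for i in idx)


@pytest.fixture()
def make_sequence(rng, matrix):
    def _make(length, background=None):
        return random_sequence(
            rng, length, matrix.background if background is None else background
        )

    return _make
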