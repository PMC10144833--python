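import numpy as np
import pytest

from csfpred.amino_acids import ALPHABET


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture()
def random_seq30(rng):
    return random_sequence(rng, 30)
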