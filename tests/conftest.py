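import numpy as np
import pytest

from promdesign.sequence_io import BASES, PromoterRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sequence():
    """Factory for random ACGT strings from a dedicated seeded stream."""
    gen = np.random.default_rng(99)

    def make(length: int) -> str:
        return "".join(gen.choice(list(BASES), size=length))

    return make


@pytest.fixture
def small_corpus(random_sequence):
    """30 random 50 bp records with log-normal strengths."""
    gen = np.random.default_rng(7)
    return [
        PromoterRecord(f"p{i:03d}", random_sequence(50), float(np.exp(gen.normal(2.0, 1.0))))
        for i in range(30)
    ]
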