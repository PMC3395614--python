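import numpy as np
import pytest

from orfunc.seq_evol import CodingSequencePair, default_grantham_table


@pytest.fixture(scope="session")
def grantham():
    return default_grantham_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_pair(nt_a: str, nt_b: str) -> CodingSequencePair:
    return CodingSequencePair.from_nucleotides("a", nt_a, "b", nt_b)


@pytest.fixture
def pair_factory():
    return make_pair
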