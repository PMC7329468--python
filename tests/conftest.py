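import numpy as np
import pytest

from norgscan.local_search import ScoringScheme, solve_karlin_altschul
from norgscan.seq_io import SequenceRecord
from norgscan.synthetic import random_sequence


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def ka_params(scheme):
    return solve_karlin_altschul(scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_seq(n: int, seed: int, gc: float = 0.5) -> str:
    return random_sequence(n, gc, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def small_subject():
    return SequenceRecord("subj", make_seq(3000, 7))
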