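import numpy as np
import pytest

from betaturn.synthetic import TurnPlan, make_corpus, make_turn_chain

# Hand-written PSI-BLAST ASCII PSSM fixture: 5 residues, alphabetical
# column order, known value 4 at (residue 3, column A).
PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
             A  C  D  E  F  G  H  I  K  L  M  N  P  Q  R  S  T  V  W  Y   A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
    1 M     -1 -2 -3 -2  0 -3 -2  1 -1  2  6 -2 -3 -1 -1 -2 -1  1 -1 -1   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0
    2 K     -1 -3 -1  1 -3 -2 -1 -3  5 -2 -1  0 -1  1  2  0 -1 -2 -3 -2   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0
    3 G      4 -2 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1 -1  1  0  0 -3 -2 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0
    4 S      1 -1  0  0 -2  0 -1 -2  0 -2 -1  1 -1  0 -1  4  1 -2 -3 -2   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0
    5 A      9 -1 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1 -1  1  0  0 -3 -2 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0

                      K         Lambda
Standard Ungapped    0.1330     0.3110
"""


@pytest.fixture(scope="session")
def pssm_text():
    return PSSM_FIXTURE


@pytest.fixture(scope="session")
def turn_chain():
    """30-mer with one planted type-I turn at residue 10."""
    plan = TurnPlan(length=30, turns=[(10, "I")])
    return make_turn_chain(plan, seed=7)


@pytest.fixture(scope="session")
def small_corpus():
    """A small high-signal corpus shared by the slower integration tests."""
    return make_corpus(n_chains=14, length_range=(30, 50), seed=11)


@pytest.fixture(scope="session")
def small_encoded(small_corpus):
    from betaturn.model import encode_corpus
    return encode_corpus(small_corpus)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
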