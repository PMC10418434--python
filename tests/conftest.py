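import numpy as np
import pytest

from deepsata.motifs import Motif

MEME_EXAMPLE = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF EX1 TF_N
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
0.9 0.1 0.0 0.0
0.0 0.0 0.2 0.8
0.3 0.7 0.0 0.0
0.0 0.0 0.6 0.4
0.8 0.2 0.0 0.0
0.0 0.0 0.3 0.7
0.4 0.6 0.0 0.0
0.0 0.0 0.9 0.1
0.7 0.3 0.0 0.0
0.0 0.0 0.4 0.6
0.1 0.9 0.0 0.0
0.0 0.0 0.8 0.2
"""

#: the same motif in the internal A,T,C,G channel order
EXAMPLE_ROWS_INTERNAL = np.array(
    [
        [0.9, 0.0, 0.1, 0.0],
        [0.0, 0.8, 0.0, 0.2],
        [0.3, 0.0, 0.7, 0.0],
        [0.0, 0.4, 0.0, 0.6],
        [0.8, 0.0, 0.2, 0.0],
        [0.0, 0.7, 0.0, 0.3],
        [0.4, 0.0, 0.6, 0.0],
        [0.0, 0.1, 0.0, 0.9],
        [0.7, 0.0, 0.3, 0.0],
        [0.0, 0.6, 0.0, 0.4],
        [0.1, 0.0, 0.9, 0.0],
        [0.0, 0.2, 0.0, 0.8],
    ]
)


@pytest.fixture
def meme_file(tmp_path):
    path = tmp_path / "motifs.meme"
    path.write_text(MEME_EXAMPLE)
    return path


@pytest.fixture
def example_motif():
    return Motif("EX1", "TF_N", EXAMPLE_ROWS_INTERNAL.copy())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_sequence(rng, n, alphabet="ATCG"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
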