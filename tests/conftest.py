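import numpy as np
import pytest

from loregic import Triplet, gate_by_alias


@pytest.fixture
def fig2_vectors():
    """The 20-sample mock triplet used in the worked scoring example.

    Per input combination: (0,0) 5 samples all T=0; (0,1) 5 samples, one
    T=1; (1,0) 5 samples all T=0; (1,1) 5 samples, four T=1.
    """
    x = np.array([0] * 10 + [1] * 10)
    y = np.array([0] * 5 + [1] * 5 + [0] * 5 + [1] * 5)
    z = np.array([0] * 5 + [0, 0, 0, 0, 1] + [0] * 5 + [1, 1, 1, 1, 0])
    return x, y, z


@pytest.fixture
def and_gate():
    return gate_by_alias("AND")


@pytest.fixture
def simple_network_file(tmp_path):
    """A, B and C all regulate T1; A also regulates B (one FFL)."""
    path = tmp_path / "edges.tsv"
    path.write_text("A\tT1\nB\tT1\nC\tT1\nA\tB\n")
    return path


def random_counts(rng, max_m=12):
    """A random, valid TripletCounts draw for property tests."""
    from loregic import TripletCounts

    m_i = tuple(int(v) for v in rng.integers(0, max_m + 1, size=4))
    n1_i = tuple(int(rng.integers(0, m + 1)) for m in m_i)
    return TripletCounts(m_i, n1_i)
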