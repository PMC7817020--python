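import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from netburden import GeneNetwork


@pytest.fixture
def path_network():
    """3-gene path A-B-C with unit weights."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return GeneNetwork(np.array(["A", "B", "C"], dtype=object), sp.csr_matrix(w), is_binary=True)


@pytest.fixture
def star_network():
    """Hub H connected to 4 leaves L1..L4, unit weights."""
    genes = np.array(["H", "L1", "L2", "L3", "L4"], dtype=object)
    w = np.zeros((5, 5))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return GeneNetwork(genes, sp.csr_matrix(w), is_binary=True)


def random_weighted_network(m, density, rng):
    """Random symmetric weighted network over m genes."""
    genes = np.array([f"G{i:03d}" for i in range(m)], dtype=object)
    w = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    mask = rng.random(iu[0].size) < density
    w[iu[0][mask], iu[1][mask]] = rng.random(mask.sum())
    w = w + w.T
    return GeneNetwork(genes, sp.csr_matrix(w))


@pytest.fixture
def toy_variants():
    """Six records spanning every filter branch; two survive the default-ish
    criteria with frameshift CADD exemption (hand-derived)."""
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(1, 7)],
            "gene": ["G1", "G1", "G1", "G2", "G2", "G3"],
            "consequence": [
                "missense",
                "missense",
                "missense",
                "frameshift",
                "other",
                "stop_gain",
            ],
            "maf": [0.02, 0.001, 0.001, 0.005, 0.003, 0.001],
            "cadd_phred": [35.0, 20.0, 25.3, np.nan, 22.0, np.nan],
        }
    )
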