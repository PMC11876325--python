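import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ratecov import io

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def master_tree() -> io.SpeciesTree:
    """((A,B),C),D with known branch lengths; 6 branches."""
    return io.parse_newick("(((A:1.0,B:2.0):0.5,C:3.0):0.25,D:4.0);")


@pytest.fixture
def toy_blm() -> io.BranchLengthMatrix:
    """3 genes x 4 branches, one missing cell."""
    df = pd.DataFrame(
        [[1.0, 2.0, 0.5, 3.0],
         [2.0, 4.0, 1.0, 6.0],
         [1.5, np.nan, 0.75, 4.5]],
        index=["g1", "g2", "g3"], columns=["A", "B", "A|B", "C"])
    return io.BranchLengthMatrix(df)


def make_erc_matrix(genes, values, n=20):
    """Build an ERCMatrix from a symmetric value dict {(a, b): erc}."""
    from ratecov import erc as erc_mod
    G = len(genes)
    V = np.full((G, G), np.nan)
    for (a, b), v in values.items():
        i, j = genes.index(a), genes.index(b)
        V[i, j] = V[j, i] = v
    counts = np.full((G, G), n, dtype=int)
    return erc_mod.ERCMatrix(
        values=pd.DataFrame(V, index=genes, columns=genes),
        n_branches=pd.DataFrame(counts, index=genes, columns=genes))
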