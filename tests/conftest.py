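import numpy as np
import pytest

from phylosyndrome.phylo import tree_from_string


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — height 2, D(A,B)=2, D(A,C)=D(B,C)=4."""
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_distances():
    """Star-phylogeny distance matrix: all off-diagonal distances 2."""

    def make(n: int) -> np.ndarray:
        D = np.full((n, n), 2.0)
        np.fill_diagonal(D, 0.0)
        return D

    return make
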