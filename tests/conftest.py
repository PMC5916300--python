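import numpy as np
import pandas as pd
import pytest

from reef_assembly.data_io import NestedCommunity
from reef_assembly.tree import PhyloTree


@pytest.fixture
def balanced4():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star5():
    return PhyloTree.from_newick("(A:2,B:2,C:2,D:2,E:2);")


@pytest.fixture
def toy_community():
    rows = [
        ("a1", "s1", "c1", "sp1", 3),
        ("a1", "s1", "c1", "sp2", 1),
        ("a1", "s1", "c2", "sp2", 4),
        ("a1", "s2", "c1", "sp1", 2),
        ("a1", "s2", "c1", "sp3", 2),
        ("a2", "s1", "c1", "sp3", 5),
        ("a2", "s1", "c2", "sp1", 1),
        ("a2", "s2", "c1", "sp2", 2),
        ("a2", "s2", "c2", "sp3", 3),
    ]
    return NestedCommunity.from_records(rows)


def random_community(rng, n_atolls=None, n_species=None):
    """Random unbalanced nested community (every colony non-empty)."""
    A = n_atolls or int(rng.integers(2, 6))
    n_sp = n_species or int(rng.integers(5, 31))
    rows = []
    for a in range(A):
        for s in range(int(rng.integers(1, 7))):
            for c in range(int(rng.integers(1, 5))):
                n_ind = int(rng.integers(1, 40))
                counts = rng.multinomial(n_ind, np.ones(n_sp) / n_sp)
                for j in np.nonzero(counts)[0]:
                    rows.append(
                        (f"a{a}", f"s{s}", f"c{c}", f"sp{j}", int(counts[j]))
                    )
    return NestedCommunity.from_records(rows)


def random_euclidean_distance(rng, n, dim=3):
    """Distances between random points: Euclidean-embeddable by design."""
    pts = rng.normal(size=(n, dim))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0
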