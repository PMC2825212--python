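import numpy as np
import pytest

from paleobrain import read_newick
from paleobrain.simulate import SimConfig, simulate_dataset


@pytest.fixture
def balanced_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return read_newick("(" + ",".join(f"s{i}:1" for i in range(12)) + ");")


@pytest.fixture(scope="session")
def small_fossil_dataset():
    """20 extant + 5 fossil tips, BM traits, no trend."""
    return simulate_dataset(SimConfig(n_extant=20, n_fossils=5, seed=3))


def random_tree(seed, n_extant=10, n_fossils=0):
    tree, _, _ = simulate_dataset(
        SimConfig(n_extant=n_extant, n_fossils=n_fossils, seed=seed))
    return tree


def brute_force_vcv(tree, taxa):
    """Independent oracle: per-pair MRCA path computation over node paths."""
    out = np.empty((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            na, nb = tree.tip(a), tree.tip(b)
            anc_a = tree.ancestors(na)
            shared = [n for n in tree.ancestors(nb) if n in set(anc_a)]
            mrca = shared[0]
            out[i, j] = tree.depths[mrca]
    return out
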