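import numpy as np
import pytest

from primereval.io import SequenceLibrary, SequenceRecord
from primereval.simulate import SimulationConfig, simulate_library, \
    simulate_tree
from primereval.tree import PhyloTree


@pytest.fixture
def tiny_library():
    return SequenceLibrary([
        SequenceRecord("s1", "ACGTACGTAC"),
        SequenceRecord("s2", "ACGTACGTAA"),
        SequenceRecord("s3", "ACGAACGTTA"),
        SequenceRecord("s4", "TCGAACGTTA"),
    ])


@pytest.fixture(scope="session")
def sim50():
    """One mid-sized seeded simulation shared across tests."""
    cfg = SimulationConfig(n_taxa=50, seed=1)
    tree, library = simulate_library(cfg)
    return cfg, tree, library


@pytest.fixture
def quartet_trees():
    t_ab = PhyloTree.from_newick("((A:1,B:1)0.6:1,(C:1,D:1):1);")
    t_ac = PhyloTree.from_newick("((A:1,C:1)0.8:1,(B:1,D:1):1);")
    return t_ab, t_ac


def random_tree(n_taxa: int, seed: int) -> PhyloTree:
    return simulate_tree(SimulationConfig(n_taxa=n_taxa, seed=seed))


def decorate_supports(tree: PhyloTree, seed: int) -> PhyloTree:
    rng = np.random.default_rng(seed)
    for node in tree.preorder():
        if not node.is_leaf and node.parent is not None:
            node.support = float(rng.random())
    return tree
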