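import numpy as np
import pytest

from caprachron import simgen
from caprachron.phylo import HaplogroupAssignment, categorize_branches
from caprachron.tree import PhyloTree


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced study bundle reused by fast tests."""
    return simgen.make_study_fixture(
        seed=11, n_codons=400, dloop_length=300,
        samples={"A": 6, "B": 5, "C": 2, "D": 3},
    )


@pytest.fixture(scope="session")
def tiny_cat():
    """3-leaf categorized tree: two haplogroup-A leaves plus the outgroup."""
    tree = PhyloTree.from_newick("((A_0:0.1,A_1:0.2):0.15,markhor:0.4);")
    hg = HaplogroupAssignment({"A_0": "A", "A_1": "A", "markhor": "outgroup"})
    return categorize_branches(tree, hg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
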