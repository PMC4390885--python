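import pytest

from mircensus.counts import CountProfile
from mircensus.treeio import PhyloTree, parse_newick


@pytest.fixture
def tree3() -> PhyloTree:
    """((A,B)N1,C)R — smallest tree with an interior node below the root."""
    return parse_newick("((A,B)N1,C)R;")


@pytest.fixture
def tree4() -> PhyloTree:
    """((A,B)N1,(C,D)N2)R — the balanced four-leaf workhorse."""
    return parse_newick("((A,B)N1,(C,D)N2)R;")


def profile(family_id: str, **counts: int) -> CountProfile:
    return CountProfile(family_id, counts)


def permute_children(tree: PhyloTree, seed: int) -> PhyloTree:
    """Same tree with every node's child order shuffled (for invariance tests)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    children = {
        v: tuple(rng.permutation(list(kids))) if len(kids) > 1 else kids
        for v, kids in tree.children.items()
    }
    return PhyloTree(tree.root, children, tree.label)
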