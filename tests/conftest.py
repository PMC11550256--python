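"""Shared fixtures: tiny hand-built networks."""

import pytest

from cherrycount import PhyloNetwork


@pytest.fixture
def star():
    """The single-node network N ≅ ⋆ (the root is a leaf)."""
    return PhyloNetwork(nodes=[0], leaf_labels={0: "a"}, root=0)


@pytest.fixture
def cherry():
    """Root with two labeled leaf children."""
    return PhyloNetwork(edges=[(0, 1), (0, 2)], leaf_labels={1: "a", 2: "b"})


@pytest.fixture
def balanced_tree():
    """((a,b)u,(c,d)v)rho: two cherries under the root."""
    return PhyloNetwork(
        edges=[(0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6)],
        leaf_labels={3: "a", 4: "b", 5: "c", 6: "d"},
    )


@pytest.fixture
def minimal_reticulated():
    """The smallest reticulated tree-child shape.

    rho=0 -> u1=1, u2=2; u1 -> l1=4, h=3; u2 -> l2=5, h; h -> l3=6.
    Both u1 and u2 root reticulated cherries.
    """
    return PhyloNetwork(
        edges=[(0, 1), (0, 2), (1, 4), (1, 3), (2, 5), (2, 3), (3, 6)],
        leaf_labels={4: "l1", 5: "l2", 6: "l3"},
    )


@pytest.fixture
def contracted_pair_network():
    """Tree-child network whose reticulation has an internal (non-leaf) child.

    rho=0 -> u1=1, u2=2; u1 -> l1=4, h=3; u2 -> l2=5, h; h -> w=6;
    w -> l3=7, l4=8.  The Hasse-diagram contraction merges {h, w}.
    """
    return PhyloNetwork(
        edges=[(0, 1), (0, 2), (1, 4), (1, 3), (2, 5), (2, 3), (3, 6), (6, 7), (6, 8)],
        leaf_labels={4: "l1", 5: "l2", 7: "l3", 8: "l4"},
    )


@pytest.fixture
def orchard_not_tree_child():
    """Orchard but not tree-child: u=1 has two reticulation children.

    rho=0 -> u=1, s=2; u -> h1=3, h2=4; s -> w=5, x=6;
    w -> lw=7, h1; x -> lx=8, h2; h1 -> l1=9; h2 -> l2=10.
    u is maximal among internal tree nodes but roots no cherry or
    reticulated cherry at the start, so no reduction sequence begins with
    it — the sequence count is strictly below the dual extension count.
    """
    return PhyloNetwork(
        edges=[
            (0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6),
            (5, 7), (5, 3), (6, 8), (6, 4), (3, 9), (4, 10),
        ],
        leaf_labels={7: "lw", 8: "lx", 9: "l1", 10: "l2"},
    )


@pytest.fixture
def non_orchard():
    """A valid binary network with no terminal node at all.

    rho=0 -> u=1, w=2; u -> h1=3, h2=4; w -> a=5, x=6; x -> h1, h2;
    h1 -> l1=7; h2 -> l2=8.  Neither u, x (no leaf child) nor w (internal
    child) is terminal, so nothing can ever be reduced.
    """
    return PhyloNetwork(
        edges=[
            (0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6),
            (6, 3), (6, 4), (3, 7), (4, 8),
        ],
        leaf_labels={5: "a", 7: "l1", 8: "l2"},
    )


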