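"""Rooted binary phylogenetic networks: data model, validation, blobs and level.

A phylogenetic network on a taxon set Sigma is a rooted directed acyclic
graph in which every node of in-degree >= 2 (a *reticulation*) has
out-degree exactly 1 and whose nodes of out-degree 0 (the *leaves*) are
bijectively labeled by Sigma.  Reticulations model hybridization and
horizontal transfer; all other nodes are *tree nodes*.  In the binary
setting every internal non-root node has degrees (in, out) in
{(1, 2), (2, 1)} and the root has (0, 2) unless the network is the
single-node network (written N ≅ ⋆).

Cherry reductions (see :mod:`cherrycount.reduction`) produce *reduced*
subnetworks that deliberately break two of the pristine rules: new leaves
appear without labels, and degree patterns such as (1, 0) arise.  Rather
than two types, :class:`PhyloNetwork` is validated under a ``mode`` flag
(``"pristine"`` or ``"reduced"``); node roles are always a pure function of
the *current* degrees.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "NodeRole",
    "Blob",
    "PhyloNetwork",
    "NetworkError",
    "classify_node",
    "validate",
    "is_tree_child",
    "internal_tree_nodes",
    "strip_leaves",
    "blobs",
    "level",
    "treewidth_upper_bound",
]


class NetworkError(ValueError):
    """Structural error in a phylogenetic network or an operation on one."""


class NodeRole(enum.Enum):
    """Role of a node, a pure function of its current in/out-degree.

    A node of in-degree >= 2 is a reticulation regardless of out-degree;
    otherwise out-degree 0 makes it a leaf, in-degree 0 the root, and the
    remaining case is an internal tree node.  The precedence matters for
    reduced networks, where an ex-reticulation that lost an in-edge and its
    out-edge is a leaf thereafter.
    """

    ROOT = "root"
    INTERNAL_TREE = "internal_tree"
    LEAF = "leaf"
    RETICULATION = "reticulation"


@dataclass(frozen=True)
class Blob:
    """A nontrivial blob: a maximal biconnected component with >= 3 nodes."""

    nodes: frozenset
    reticulation_count: int


class PhyloNetwork:
    """A rooted DAG with (partially) labeled leaves.

    Node identifiers are opaque, stable integers: reductions never renumber
    or reuse them, so a node can be identified across a whole reduction
    sequence and every reduced network is literally a subnetwork (its nodes
    and edges are nodes and edges of the original).

    Parameters
    ----------
    edges:
        Iterable of ``(parent, child)`` pairs.  Loops and duplicate edges
        are rejected.
    leaf_labels:
        Partial mapping node -> taxon label.
    root:
        Optional explicit root; inferred as the unique in-degree-0 node
        when omitted.
    nodes:
        Optional extra nodes (needed for the single-node network, which
        has no edges).
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        leaf_labels: Optional[dict] = None,
        root=None,
        nodes: Iterable = (),
        node_names: Optional[dict] = None,
    ):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise NetworkError(f"loop edge on node {u!r}")
            if g.has_edge(u, v):
                raise NetworkError(f"parallel edge {u!r} -> {v!r}")
            g.add_edge(u, v)
        if len(g) == 0:
            raise NetworkError("a phylogenetic network has at least one node")
        self._g = g
        if root is None:
            sources = [v for v in g if g.in_degree(v) == 0]
            if len(sources) != 1:
                raise NetworkError(
                    f"expected exactly one in-degree-0 node, found {len(sources)}"
                )
            root = sources[0]
        elif root not in g:
            raise NetworkError(f"declared root {root!r} is not a node")
        self.root = root
        self.leaf_labels = dict(leaf_labels or {})
        for v in self.leaf_labels:
            if v not in g:
                raise NetworkError(f"label attached to unknown node {v!r}")
        # purely cosmetic display names (e.g. from an input file); never used
        # by any algorithm
        self.node_names = dict(node_names or {})

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying directed graph (treat as read-only)."""
        return self._g

    def nodes(self) -> list:
        return list(self._g.nodes)

    def edges(self) -> list:
        return list(self._g.edges)

    def __len__(self) -> int:
        return len(self._g)

    def __contains__(self, v) -> bool:
        return v in self._g

    def in_degree(self, v) -> int:
        return self._g.in_degree(v)

    def out_degree(self, v) -> int:
        return self._g.out_degree(v)

    def children(self, v) -> list:
        return list(self._g.successors(v))

    def parents(self, v) -> list:
        return list(self._g.predecessors(v))

    def leaves(self) -> list:
        return [v for v in self._g if self._g.out_degree(v) == 0]

    def reticulations(self) -> list:
        return [v for v in self._g if self._g.in_degree(v) >= 2]

    def tree_nodes(self) -> list:
        """All nodes of in-degree <= 1 (leaves and the root included)."""
        return [v for v in self._g if self._g.in_degree(v) <= 1]

    def is_single_node(self) -> bool:
        return len(self._g) == 1

    def copy(self) -> "PhyloNetwork":
        new = object.__new__(PhyloNetwork)
        new._g = self._g.copy()
        new.root = self.root
        new.leaf_labels = dict(self.leaf_labels)
        new.node_names = dict(self.node_names)
        return new

    def display_name(self, v) -> str:
        """Best human-readable name for a node: label, input name, or id."""
        return self.leaf_labels.get(v) or self.node_names.get(v) or str(v)

    def label_of(self, v) -> Optional[str]:
        return self.leaf_labels.get(v)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PhyloNetwork({len(self._g)} nodes, {self._g.number_of_edges()} "
            f"edges, {len(self.leaves())} leaves, "
            f"{len(self.reticulations())} reticulations)"
        )


# -- node roles -------------------------------------------------------------


def classify_node(N: PhyloNetwork, v) -> NodeRole:
    """Classify ``v`` by its current degrees.

    Reticulation (in-degree >= 2) takes precedence, then leaf (out-degree
    0), then root (in-degree 0), else internal tree node.
    """
    if v not in N:
        raise KeyError(f"unknown node identifier {v!r}")
    g = N.graph
    if g.in_degree(v) >= 2:
        return NodeRole.RETICULATION
    if g.out_degree(v) == 0:
        return NodeRole.LEAF
    if g.in_degree(v) == 0:
        return NodeRole.ROOT
    return NodeRole.INTERNAL_TREE


def internal_tree_nodes(N: PhyloNetwork) -> set:
    """The set T(N̊): nodes of out-degree >= 1 and in-degree <= 1.

    Equivalently, the tree nodes of the leaf-stripped rDAG N̊.
    """
    g = N.graph
    return {v for v in g if g.out_degree(v) >= 1 and g.in_degree(v) <= 1}


# -- validation --------------------------------------------------------------

_REDUCED_DEGREES = {(0, 0), (0, 2), (1, 0), (1, 2), (2, 1)}


def validate(N: PhyloNetwork, mode: str = "pristine") -> list[str]:
    """Return a report of violated invariants (empty iff valid).

    ``pristine`` enforces the full definition of a binary phylogenetic
    network: rooted DAG, binary degrees, no elementary nodes, reticulation
    out-degree 1, and a leaf-label bijection.  ``reduced`` is the relaxed
    regime of subnetworks produced by cherry reductions: labels and the
    no-elementary-node rule are not enforced and degrees are checked
    against the patterns reductions can actually create.
    """
    if mode not in ("pristine", "reduced"):
        raise ValueError(f"unknown validation mode {mode!r}")
    g = N.graph
    report: list[str] = []

    if not nx.is_directed_acyclic_graph(g):
        report.append("graph contains a directed cycle")
        return report

    sources = [v for v in g if g.in_degree(v) == 0]
    if len(sources) != 1:
        report.append(f"rooted violation: {len(sources)} nodes of in-degree 0")
    elif sources[0] != N.root:
        report.append(
            f"declared root {N.root!r} differs from the in-degree-0 node"
        )
    reachable = {N.root} | nx.descendants(g, N.root) if N.root in g else set()
    if reachable != set(g.nodes):
        stranded = sorted(set(g.nodes) - reachable, key=repr)
        report.append(f"nodes not reachable from the root: {stranded}")

    if N.is_single_node():
        # N ≅ ⋆: the root is a leaf; nothing more to check on degrees.
        pass
    elif mode == "pristine":
        for v in g:
            d = (g.in_degree(v), g.out_degree(v))
            if v == N.root:
                if d != (0, 2):
                    report.append(f"root degree violation at {v!r}: {d}")
            elif d[1] == 0:
                if d[0] != 1:
                    report.append(f"leaf {v!r} has in-degree {d[0]}")
            elif d not in ((1, 2), (2, 1)):
                report.append(f"binary degree violation at {v!r}: {d}")
            if d == (1, 1):
                report.append(f"elementary node {v!r}")
            if d[0] >= 2 and d[1] != 1:
                report.append(
                    f"reticulation {v!r} has out-degree {d[1]}, expected 1"
                )
    else:
        for v in g:
            d = (g.in_degree(v), g.out_degree(v))
            if d not in _REDUCED_DEGREES:
                report.append(f"degree pattern {d} at {v!r} not reachable by reductions")

    if mode == "pristine":
        leaves = N.leaves()
        unlabeled = [v for v in leaves if v not in N.leaf_labels]
        if unlabeled:
            report.append(f"unlabeled leaves: {sorted(unlabeled, key=repr)}")
        labels = [N.leaf_labels[v] for v in leaves if v in N.leaf_labels]
        if len(set(labels)) != len(labels):
            report.append("duplicate leaf labels")
        nonleaf_labeled = [v for v in N.leaf_labels if g.out_degree(v) != 0]
        if nonleaf_labeled:
            report.append(
                f"labels on non-leaf nodes: {sorted(nonleaf_labeled, key=repr)}"
            )

    return report


def is_tree_child(N: PhyloNetwork) -> bool:
    """True iff every internal node has at least one tree-node child.

    Evaluated against current degrees, so the test is meaningful on
    reduced networks as well: a child counts as tree-type when its
    in-degree is <= 1.
    """
    g = N.graph
    for v in g:
        if g.out_degree(v) == 0:
            continue
        if not any(g.in_degree(c) <= 1 for c in g.successors(v)):
            return False
    return True


# -- leaf stripping, blobs, level -------------------------------------------


def strip_leaves(N: PhyloNetwork) -> nx.DiGraph:
    """The rDAG N̊: remove all leaves and their incident edges.

    Returns a plain directed graph (it may be empty, when N ≅ ⋆, so it is
    not itself a phylogenetic network).
    """
    g = N.graph
    keep = [v for v in g if g.out_degree(v) >= 1]
    return g.subgraph(keep).copy()


def blobs(N: PhyloNetwork) -> list[Blob]:
    """Nontrivial blobs: maximal biconnected components with >= 3 nodes.

    Biconnectivity is taken on the underlying undirected graph; the
    reticulation count of a blob is the number of its nodes with in-degree
    >= 2 in N.  Components of size 2 (single edges, i.e. bridges) are
    trivial and excluded — every nontrivial blob contains a reticulation.
    """
    g = N.graph
    und = g.to_undirected()
    out = []
    for comp in nx.biconnected_components(und):
        if len(comp) >= 3:
            r = sum(1 for v in comp if g.in_degree(v) >= 2)
            out.append(Blob(nodes=frozenset(comp), reticulation_count=r))
    return out


def level(N: PhyloNetwork) -> int:
    """The level: maximum reticulation count over blobs (0 for trees)."""
    bs = blobs(N)
    return max((b.reticulation_count for b in bs), default=0)


def treewidth_upper_bound(level_k: int, reticulations_r: int) -> tuple[int, int]:
    """Upper bounds on tree-width from level and reticulation number.

    For a level-k network with r reticulations, tw(N) <= k + 1 <= r + 1;
    both bounds are returned as ``(k + 1, r + 1)``.
    """
    if level_k < 0 or reticulations_r < 0:
        raise ValueError("level and reticulation count must be nonnegative")
    if level_k > reticulations_r:
        raise ValueError(
            f"level {level_k} cannot exceed the reticulation count {reticulations_r}"
        )
    return (level_k + 1, reticulations_r + 1)
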