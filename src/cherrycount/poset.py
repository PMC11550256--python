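"""Finite posets, reachability orders, duals, and Hasse diagram construction.

The poset of interest is the reachability order on the internal tree nodes
T(N̊) of a network N: ``x ≼ y`` iff there is a directed path from x to y
(possibly through nodes outside the subset).  Its Hasse diagram — here
:class:`CoverGraph` — can be computed two independent ways:

* :func:`transitive_reduction_oracle` applies the definition of a cover
  (``x ≺· y`` iff ``x ≺ y`` with no element strictly between) directly, in
  cubic time; it is the oracle used in tests.
* :func:`cover_graph_by_contraction` builds the same graph for a binary
  tree-child network *without* computing reachability at all: strip the
  leaves, drop reticulations whose child was a leaf, and contract every
  remaining reticulation into its (necessarily tree-type) child.  The
  result is a minor of N, which is what bounds the tree-width of the cover
  graph by that of the network.

Posets are stored with their full reflexive-transitive closure; networks
in this domain are small (|T(N̊)| = |Σ| + r − 1), and closure makes
comparability queries O(1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional

import networkx as nx

from .network import NetworkError, PhyloNetwork, internal_tree_nodes, is_tree_child

__all__ = [
    "Poset",
    "CoverGraph",
    "QuotMap",
    "DISCARDED",
    "reachability_poset",
    "dualize",
    "transitive_reduction_oracle",
    "cover_graph_by_contraction",
    "poset_from_cover_graph",
]

#: Sentinel index in a :class:`QuotMap` for nodes absent from the quotient.
DISCARDED = -1


def _sorted_elems(elems):
    try:
        return tuple(sorted(elems))
    except TypeError:
        return tuple(sorted(elems, key=repr))


class Poset:
    """A finite partially ordered set stored as its strict-order closure.

    Parameters
    ----------
    elements:
        The ground set.
    strict_pairs:
        Pairs ``(x, y)`` with ``x ≺ y``; the transitive closure is taken,
        and reflexivity is implicit.  Antisymmetry (acyclicity) is checked.
    """

    def __init__(self, elements: Iterable[Hashable], strict_pairs: Iterable[tuple] = ()):
        self.elements: tuple = _sorted_elems(elements)
        elem_set = set(self.elements)
        if len(elem_set) != len(self.elements):
            raise ValueError("duplicate poset elements")
        g = nx.DiGraph()
        g.add_nodes_from(self.elements)
        for x, y in strict_pairs:
            if x not in elem_set or y not in elem_set:
                raise ValueError(f"relation pair ({x!r}, {y!r}) outside the ground set")
            if x == y:
                raise ValueError(f"strict relation {x!r} ≺ {x!r} is reflexive")
            g.add_edge(x, y)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("relation is not antisymmetric (contains a cycle)")
        # strict up-sets: above[x] = {y : x ≺ y}
        self._above: dict = {x: frozenset(nx.descendants(g, x)) for x in self.elements}

    # -- queries -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, x) -> bool:
        return x in self._above

    def lt(self, x, y) -> bool:
        """x ≺ y (strictly)."""
        return y in self._above[x]

    def le(self, x, y) -> bool:
        """x ≼ y."""
        return x == y or y in self._above[x]

    def comparable(self, x, y) -> bool:
        return x == y or self.lt(x, y) or self.lt(y, x)

    def strictly_above(self, x) -> frozenset:
        return self._above[x]

    def strictly_below(self, x) -> frozenset:
        return frozenset(y for y in self.elements if x in self._above[y])

    def strict_pairs(self) -> set[tuple]:
        return {(x, y) for x in self.elements for y in self._above[x]}

    def maximal_elements(self) -> set:
        return {x for x in self.elements if not self._above[x]}

    def minimal_elements(self) -> set:
        return {x for x in self.elements if all(x not in self._above[y] for y in self.elements)}

    def is_antichain(self) -> bool:
        return all(not up for up in self._above.values())

    def is_total_order(self) -> bool:
        n = len(self.elements)
        return sorted(len(up) for up in self._above.values()) == list(range(n))

    def is_linear_extension(self, order: Iterable) -> bool:
        """Does ``order`` list all elements, smaller-before-larger?"""
        seq = list(order)
        if sorted(seq, key=repr) != sorted(self.elements, key=repr):
            return False
        pos = {x: i for i, x in enumerate(seq)}
        return all(pos[x] < pos[y] for (x, y) in self.strict_pairs())

    def comparability_components(self) -> list[set]:
        """Connected components of the comparability graph."""
        g = nx.Graph()
        g.add_nodes_from(self.elements)
        g.add_edges_from(self.strict_pairs())
        return [set(c) for c in nx.connected_components(g)]

    def restrict(self, subset: Iterable) -> "Poset":
        sub = set(subset)
        pairs = [(x, y) for (x, y) in self.strict_pairs() if x in sub and y in sub]
        return Poset(sub, pairs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Poset):
            return NotImplemented
        return self.elements == other.elements and self._above == other._above

    def __hash__(self):
        return hash((self.elements, tuple(sorted(self._above.items(), key=repr))))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Poset({len(self.elements)} elements, {len(self.strict_pairs())} strict pairs)"


@dataclass(frozen=True)
class CoverGraph:
    """The Hasse diagram: edges are exactly the cover relations x ≺· y."""

    nodes: tuple
    edges: frozenset

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class QuotMap:
    """Mapping network node → cover-graph index produced by contraction.

    Leaves (and reticulations whose only child was a leaf) map to the
    sentinel :data:`DISCARDED`; each internal tree node maps to a unique
    index; each surviving reticulation maps to the index of its tree-node
    child, i.e. the two form a contracted class of size 2.
    """

    mapping: Mapping

    def __getitem__(self, v) -> int:
        return self.mapping[v]

    def classes(self) -> dict[int, set]:
        """Index → the set of network nodes contracted into it."""
        out: dict[int, set] = {}
        for v, i in self.mapping.items():
            if i != DISCARDED:
                out.setdefault(i, set()).add(v)
        return out


# -- constructions ------------------------------------------------------------


def reachability_poset(N: PhyloNetwork, subset: Optional[Iterable] = None) -> Poset:
    """The reachability order of N restricted to ``subset``.

    ``x ≼ y`` iff a directed path x ⇝ y exists in N — the path may pass
    through nodes outside the subset.  Defaults to T(N̊).
    """
    X = set(subset) if subset is not None else internal_tree_nodes(N)
    unknown = X - set(N.graph.nodes)
    if unknown:
        raise NetworkError(f"subset contains non-nodes: {sorted(unknown, key=repr)}")
    g = N.graph
    pairs = []
    for x in X:
        reach = nx.descendants(g, x)
        pairs.extend((x, y) for y in reach & X)
    return Poset(X, pairs)


def dualize(P: Poset) -> Poset:
    """The order-dual P^op: x ≼ y in the dual iff y ≼ x in P."""
    return Poset(P.elements, [(y, x) for (x, y) in P.strict_pairs()])


def transitive_reduction_oracle(P: Poset) -> CoverGraph:
    """Covers by the definition: x ≺· y iff x ≺ y and no z with x ≺ z ≺ y.

    Cubic time; intended as the independent oracle for
    :func:`cover_graph_by_contraction` on small posets.
    """
    edges = set()
    for x in P.elements:
        for y in P.strictly_above(x):
            if not any(P.lt(x, z) and P.lt(z, y) for z in P.elements):
                edges.add((x, y))
    return CoverGraph(nodes=P.elements, edges=frozenset(edges))


def cover_graph_by_contraction(N: PhyloNetwork) -> tuple[CoverGraph, QuotMap]:
    """Hasse diagram of the reachability poset on T(N̊) by edge contraction.

    For a pristine binary tree-child network: discard the leaves, discard
    every reticulation whose out-degree in N̊ is 0 (its only child was a
    leaf), and contract each surviving reticulation into its child — the
    tree-child condition guarantees that child is a tree node.  A single
    linear pass over the nodes builds the quotient map; mapping every edge
    of N through it yields a DAG whose reachability closure is exactly the
    poset on T(N̊).

    One subtlety: when the two parents of a reticulation are themselves
    comparable (an ancestor of an internal tree node also feeds the
    reticulation above it), the raw contraction contains a transitive
    shortcut in addition to the covers, so it is a supergraph of the Hasse
    diagram with the same closure.  A final transitive reduction of the
    (small) contracted DAG removes those shortcuts; edge deletion keeps the
    result a minor of N, so the tree-width bound tw(cover) <= tw(N) is
    preserved.

    Returns the cover graph on integer indices together with the
    :class:`QuotMap` naming them.
    """
    if not is_tree_child(N):
        raise NetworkError(
            "cover graph by contraction requires a tree-child network: "
            "a reticulation's child might otherwise not be a tree node"
        )
    g = N.graph
    quot: dict = {}
    order = _sorted_elems(g.nodes)
    # first pass: leaves out, internal tree nodes to fresh indices
    next_index = 0
    for v in order:
        if g.out_degree(v) == 0:
            quot[v] = DISCARDED
        elif g.in_degree(v) <= 1:
            quot[v] = next_index
            next_index += 1
    # second pass: reticulations follow their single child
    for v in order:
        if v in quot:
            continue
        (child,) = g.successors(v)
        if g.in_degree(child) >= 2:
            raise NetworkError(
                f"reticulation {v!r} has a reticulation child {child!r}; "
                "not a binary tree-child network"
            )
        # child is a leaf -> v had out-degree 0 in N̊ and is discarded
        quot[v] = quot[child]

    q = nx.DiGraph()
    q.add_nodes_from(range(next_index))
    for u, v in g.edges:
        qu, qv = quot[u], quot[v]
        if qu != DISCARDED and qv != DISCARDED and qu != qv:
            q.add_edge(qu, qv)
    reduced = nx.transitive_reduction(q)
    cover = CoverGraph(
        nodes=tuple(range(next_index)), edges=frozenset(reduced.edges)
    )
    return cover, QuotMap(mapping=quot)


def poset_from_cover_graph(cover: CoverGraph) -> Poset:
    """Reconstruct the poset whose Hasse diagram is ``cover``."""
    return Poset(cover.nodes, cover.edges)
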