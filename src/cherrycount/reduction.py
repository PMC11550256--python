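"""Cherry reductions: terminal nodes, the CR operation, orchard recognition,
exhaustive sequence enumeration, and the correspondence with linear
extensions.

A *cherry* is a pair of leaves with a common parent; a *reticulated cherry*
is a leaf whose sibling is a reticulation whose single child is a leaf.  An
internal tree node rooting either is *terminal*.  The cherry reduction
CR(N, u) of a terminal node u removes every edge below u and every strict
descendant of u that is a tree node; a descendant reticulation keeps its
other in-edge and becomes a new leaf, and u itself becomes a leaf.  A
network reducible to a single node this way is an *orchard* network; all
binary tree-child networks are orchard.

For tree-child networks the terminal nodes are exactly the maximal elements
of the reachability poset on T(N̊), which makes the sequence-to-permutation
map a bijection onto the linear extensions of the dual poset: reversing a
reduction sequence yields a linear extension of T(N̊) itself and vice
versa.  :func:`enumerate_cr_sequences` is the brute-force side of that
equivalence; the counting side lives in :mod:`cherrycount.lecount`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .network import (
    NetworkError,
    PhyloNetwork,
    internal_tree_nodes,
    is_tree_child,
)
from .poset import reachability_poset

__all__ = [
    "TerminalKind",
    "CRSequence",
    "ReductionError",
    "terminal_nodes",
    "cherry_reduce",
    "is_orchard",
    "enumerate_cr_sequences",
    "crseq_to_linext",
    "linext_to_crseq",
]

#: Default cap on |T(N̊)| for exhaustive enumeration (worst case 10! paths).
DEFAULT_ENUMERATION_GUARD = 10


class ReductionError(NetworkError):
    """A cherry reduction precondition failed."""


class TerminalKind(enum.Enum):
    CHERRY = "cherry"
    RETICULATED_CHERRY = "reticulated_cherry"


@dataclass(frozen=True)
class CRSequence:
    """A complete cherry reduction sequence of a network.

    ``reduced_nodes`` lists, in order, the terminal node reduced at each
    step; a complete sequence has length |T(N̊)| and ends with the root.
    """

    reduced_nodes: tuple

    def __len__(self) -> int:
        return len(self.reduced_nodes)

    def __iter__(self):
        return iter(self.reduced_nodes)


def _sorted_nodes(nodes):
    try:
        return sorted(nodes)
    except TypeError:
        return sorted(nodes, key=repr)


def terminal_nodes(N: PhyloNetwork) -> dict:
    """Map each terminal node to its :class:`TerminalKind`.

    Evaluated on current degrees, so it works mid-reduction: a node is the
    root of a cherry when both children are leaves, and of a reticulated
    cherry when one child is a leaf and the other is a reticulation whose
    single child is a leaf.
    """
    g = N.graph
    out: dict = {}
    for v in g:
        if g.out_degree(v) == 0 or g.in_degree(v) >= 2:
            continue
        kids = list(g.successors(v))
        leaf_kids = [c for c in kids if g.out_degree(c) == 0 and g.in_degree(c) <= 1]
        if len(kids) == 2 and len(leaf_kids) == 2:
            out[v] = TerminalKind.CHERRY
            continue
        if len(kids) == 2 and len(leaf_kids) == 1:
            (other,) = [c for c in kids if c not in leaf_kids]
            if g.in_degree(other) >= 2 and g.out_degree(other) == 1:
                (grandchild,) = g.successors(other)
                if g.out_degree(grandchild) == 0:
                    out[v] = TerminalKind.RETICULATED_CHERRY
    return out


def cherry_reduce(N: PhyloNetwork, u) -> PhyloNetwork:
    """CR(N, u): reduce the cherry or reticulated cherry rooted at u.

    Removes every edge whose tail is a (weak) descendant of u and every
    strict descendant of u that is currently a tree node.  A descendant
    reticulation survives with its remaining in-edge and becomes a leaf; u
    becomes a leaf.  Node identifiers are untouched, so the result is a
    literal subnetwork of N.
    """
    kinds = terminal_nodes(N)
    if u not in kinds:
        if u not in N:
            raise KeyError(f"unknown node identifier {u!r}")
        raise ReductionError(
            f"node {u!r} is not terminal: it roots neither a cherry "
            "(two leaf children) nor a reticulated cherry (a leaf child and "
            "a reticulation child whose single child is a leaf)"
        )
    g = N.graph
    descendants = nx.descendants(g, u)  # strict
    weak = descendants | {u}
    new = N.copy()
    ng = new._g
    ng.remove_edges_from([(a, b) for (a, b) in g.edges if a in weak])
    doomed = [v for v in descendants if g.in_degree(v) <= 1]
    ng.remove_nodes_from(doomed)
    for v in doomed:
        new.leaf_labels.pop(v, None)
        new.node_names.pop(v, None)
    return new


def is_orchard(N: PhyloNetwork) -> bool:
    """True iff iterated cherry reductions take N down to a single node.

    Greedily reduces an arbitrary terminal node until none remains; this is
    decisive because all complete reduction sequences of a network have the
    same length, so getting stuck above one node means no sequence exists.
    """
    cur = N
    while not cur.is_single_node():
        terms = terminal_nodes(cur)
        if not terms:
            return False
        cur = cherry_reduce(cur, _sorted_nodes(terms)[0])
    return True


def enumerate_cr_sequences(
    N: PhyloNetwork, max_nodes: int = DEFAULT_ENUMERATION_GUARD
) -> list[CRSequence]:
    """All complete cherry reduction sequences of N, by depth-first search.

    At every step each terminal node is tried in ascending identifier
    order, so the returned list is reproducible.  Returns one empty
    sequence for the single-node network and the empty list iff N is not
    orchard.  Guarded by ``max_nodes`` on |T(N̊)| (worst case factorial
    growth); use the counting routines for anything larger.
    """
    p = len(internal_tree_nodes(N))
    if p > max_nodes:
        raise ReductionError(
            f"|T(N̊)| = {p} exceeds the enumeration guard {max_nodes}; "
            "use count_cherry_sequences instead"
        )
    results: list[CRSequence] = []
    prefix: list = []

    def dfs(cur: PhyloNetwork):
        if cur.is_single_node():
            results.append(CRSequence(tuple(prefix)))
            return
        for u in _sorted_nodes(terminal_nodes(cur)):
            prefix.append(u)
            dfs(cherry_reduce(cur, u))
            prefix.pop()

    dfs(N)
    return results


def replay(N: PhyloNetwork, nodes: Iterable) -> list[PhyloNetwork]:
    """Apply reductions in order; return the full trajectory (N first).

    Raises :class:`ReductionError` naming the first failing step.
    """
    traj = [N]
    for step, u in enumerate(nodes):
        try:
            traj.append(cherry_reduce(traj[-1], u))
        except (ReductionError, KeyError) as exc:
            raise ReductionError(f"replay failed at step {step} ({u!r}): {exc}") from exc
    return traj


def crseq_to_linext(N: PhyloNetwork, S: CRSequence) -> tuple:
    """Map a reduction sequence to a linear extension of T(N̊): reverse it.

    The sequence itself lists maximal elements first, i.e. it is a linear
    extension of the dual order; reversal gives one of the order itself.
    The sequence is validated by replaying it.
    """
    traj = replay(N, S.reduced_nodes)
    if not traj[-1].is_single_node():
        raise ReductionError(
            f"sequence of length {len(S)} is incomplete: "
            f"{len(traj[-1])} nodes remain"
        )
    return tuple(reversed(S.reduced_nodes))


def linext_to_crseq(N: PhyloNetwork, pi: Iterable) -> CRSequence:
    """Replay a linear extension of the dual order as a reduction sequence.

    ``pi`` must list T(N̊) maximal-elements-first (equivalently, be the
    reversal of a linear extension of T(N̊)).  Requires a tree-child
    network — for general orchard networks a maximal internal tree node
    need not start any reduction sequence.
    """
    if not is_tree_child(N):
        raise ReductionError(
            "replaying a linear extension requires a tree-child network: "
            "in a general orchard network a maximal internal tree node may "
            "start no cherry reduction sequence"
        )
    order = tuple(pi)
    P = reachability_poset(N)
    if set(order) != set(P.elements) or len(order) != len(P.elements):
        raise ReductionError("order is not a permutation of T(N̊)")
    pos = {x: i for i, x in enumerate(order)}
    for x, y in P.strict_pairs():
        # dual extension: larger (deeper) elements come first
        if pos[x] < pos[y]:
            raise ReductionError(
                f"order violates the dual reachability order: {x!r} ≺ {y!r} "
                f"in N but {x!r} is listed first"
            )
    replay(N, order)  # raises on any failing step
    return CRSequence(reduced_nodes=order)
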