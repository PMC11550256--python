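"""Graph minors of phylogenetic networks and level lower bounds.

A minor of (the underlying undirected graph of) a network is described by a
:class:`MinorSpec`: a partition of a node subset into connected classes,
plus the class pairs declared adjacent.  Contracting each class to a point
yields the minor.  Minors drive two bounds used here:

* a K_n minor forces tree-width >= n − 1;
* a biconnected minor H forces level >= |E(H)| − |V(H)| + 1, because under
  any orientation induced by the network each class of oriented in-degree
  d must contain at least d − 1 reticulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .network import NetworkError, PhyloNetwork

__all__ = [
    "MinorSpec",
    "minor_violations",
    "verify_minor",
    "induced_orientation",
    "check_reticulations_per_class",
    "level_lower_bound_from_minor",
    "clique_level_bound",
    "grid_level_bound",
]


@dataclass(frozen=True)
class MinorSpec:
    """A minor as a quotient: named connected classes + declared adjacencies.

    ``classes`` maps class name -> frozenset of network nodes (pairwise
    disjoint); ``declared_edges`` holds unordered pairs of class names.
    """

    classes: Mapping[str, frozenset]
    declared_edges: frozenset

    @staticmethod
    def make(classes: Mapping[str, Iterable], declared_edges: Iterable) -> "MinorSpec":
        return MinorSpec(
            classes={k: frozenset(v) for k, v in classes.items()},
            declared_edges=frozenset(frozenset(e) for e in declared_edges),
        )

    def class_of(self) -> dict:
        """Network node -> class name."""
        out: dict = {}
        for name, members in self.classes.items():
            for v in members:
                out[v] = name
        return out


def _quotient_edges(N: PhyloNetwork, spec: MinorSpec) -> set[frozenset]:
    """Unordered class pairs witnessed by at least one network edge."""
    cls = spec.class_of()
    out = set()
    for u, v in N.graph.edges:
        cu, cv = cls.get(u), cls.get(v)
        if cu is not None and cv is not None and cu != cv:
            out.add(frozenset((cu, cv)))
    return out


def minor_violations(N: PhyloNetwork, spec: MinorSpec) -> list[str]:
    """Detailed report of MinorSpec invariant violations (empty iff valid)."""
    report: list[str] = []
    seen: dict = {}
    und = N.graph.to_undirected(as_view=True)
    for name, members in spec.classes.items():
        for v in members:
            if v not in N:
                report.append(f"class {name!r} contains non-node {v!r}")
            if v in seen:
                report.append(
                    f"node {v!r} appears in classes {seen[v]!r} and {name!r}"
                )
            seen[v] = name
        present = [v for v in members if v in N]
        if present and not nx.is_connected(und.subgraph(present)):
            report.append(f"class {name!r} does not induce a connected subgraph")
    witnessed = _quotient_edges(N, spec)
    for e in spec.declared_edges:
        if e not in witnessed:
            a, b = tuple(e)
            report.append(f"declared edge {a!r}–{b!r} has no witnessing network edge")
    return report


def verify_minor(N: PhyloNetwork, spec: MinorSpec, target: nx.Graph) -> bool:
    """Is the quotient of ``spec`` a valid minor of N isomorphic to ``target``?

    Checks all MinorSpec invariants and that the quotient's edge set equals
    the target graph's up to class naming (graph isomorphism).
    """
    if minor_violations(N, spec):
        return False
    q = nx.Graph()
    q.add_nodes_from(spec.classes)
    q.add_edges_from(tuple(e) for e in _quotient_edges(N, spec))
    return nx.is_isomorphic(q, target)


def induced_orientation(N: PhyloNetwork, spec: MinorSpec) -> dict:
    """One orientation of the declared edges induced by N.

    Maps each declared class pair to an ordered (tail, head) tuple
    witnessed by a directed network edge; the first witness in node order
    is used, so the result is deterministic (other orientations may exist).
    """
    cls = spec.class_of()
    orientation: dict = {}

    def key(e):
        return tuple(repr(x) for x in e)

    for u, v in sorted(N.graph.edges, key=key):
        cu, cv = cls.get(u), cls.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        pair = frozenset((cu, cv))
        if pair in spec.declared_edges and pair not in orientation:
            orientation[pair] = (cu, cv)
    return orientation


def check_reticulations_per_class(
    N: PhyloNetwork, spec: MinorSpec, orientation: Mapping
) -> list[dict]:
    """Per-class reticulation audit under an induced orientation.

    Each directed class edge must be witnessed by a directed network edge
    between the classes (else a witness error is raised).  A class of
    oriented in-degree d >= 1 is a weakly connected subgraph entered by d
    edges, so it must contain at least d − 1 reticulations of N.  Returns
    one record per class: ``{"class", "in_degree", "reticulations",
    "satisfied"}`` — always satisfied for genuinely induced orientations.
    """
    cls = spec.class_of()
    directed_witness = set()
    for u, v in N.graph.edges:
        cu, cv = cls.get(u), cls.get(v)
        if cu is not None and cv is not None and cu != cv:
            directed_witness.add((cu, cv))
    in_deg: dict = {name: 0 for name in spec.classes}
    for pair, (tail, head) in orientation.items():
        if frozenset((tail, head)) != frozenset(pair):
            raise NetworkError(f"orientation of {pair!r} names other classes")
        if (tail, head) not in directed_witness:
            raise NetworkError(
                f"orientation {tail!r} -> {head!r} is not induced by any "
                "network edge"
            )
        in_deg[head] += 1
    g = N.graph
    report = []
    for name, members in spec.classes.items():
        retics = sum(1 for v in members if v in N and g.in_degree(v) >= 2)
        need = max(in_deg[name] - 1, 0)
        report.append(
            {
                "class": name,
                "in_degree": in_deg[name],
                "reticulations": retics,
                "satisfied": retics >= need,
            }
        )
    return report


# -- bound formulas -----------------------------------------------------------


def level_lower_bound_from_minor(num_nodes: int, num_edges: int) -> int:
    """Level lower bound |E(H)| − |V(H)| + 1 from a biconnected minor H."""
    if num_nodes < 0 or num_edges < 0:
        raise ValueError("node and edge counts must be nonnegative")
    return max(num_edges - num_nodes + 1, 0)


def clique_level_bound(n: int) -> int:
    """Level lower bound (n−1)(n−2)/2 from a K_n minor."""
    if n < 1:
        raise ValueError("n must be positive")
    return (n - 1) * (n - 2) // 2


def grid_level_bound(n: int, m: int) -> int:
    """Level lower bound (n−1)(m−1) from an n×m grid or K_{n,m} minor."""
    if n < 1 or m < 1:
        raise ValueError("grid dimensions must be positive")
    return (n - 1) * (m - 1)
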