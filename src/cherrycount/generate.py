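"""Synthetic network generators.

Two generators are provided:

* :func:`generate_random_tree_child` grows a random binary tree-child
  network from a single node by reversing cherry reductions: splitting a
  leaf into a cherry, or turning an ordered pair of leaves into a
  reticulated cherry.  Because growth is the reverse of a reduction
  sequence, every generated network is orchard by construction; moves that
  would break the tree-child condition are rejected and redrawn.
  :func:`generate_random_orchard` is the same engine without the rejection,
  and produces (binary, orchard) networks that are frequently *not*
  tree-child — the regime where the terminal-node/maximal-element
  correspondence fails.

* :func:`build_clique_minor_network` constructs, for each n >= 3, an
  explicit binary tree-child network whose underlying graph has a K_n
  minor, with exactly (n−1)(n−2)/2 reticulations in a single blob.  It
  witnesses that tree-child networks have unbounded tree-width (>= n − 1
  from the clique minor) while their level grows only quadratically in n.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

from .minors import MinorSpec
from .network import NetworkError, PhyloNetwork

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "generate_random_tree_child",
    "generate_random_orchard",
    "build_clique_minor_network",
]


class GenerationError(NetworkError):
    """The generator could not satisfy its constraints."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random growth generator.

    Identical configs produce identical networks, node identifiers
    included.
    """

    num_leaves: int
    num_reticulations: int = 0
    seed: int = 0
    max_rejections: int = 10000

    def __post_init__(self):
        if self.num_leaves < 1:
            raise ValueError("num_leaves must be >= 1")
        if self.num_reticulations < 0:
            raise ValueError("num_reticulations must be >= 0")


class _Stuck(Exception):
    """Growth dead-ended; the caller restarts with the advanced RNG."""


def _grow(cfg: GeneratorConfig, tree_child: bool) -> PhyloNetwork:
    rng = random.Random(cfg.seed)
    rejections = 0
    while True:
        try:
            return _grow_once(cfg, tree_child, rng)
        except _Stuck:
            rejections += 1
            if rejections > cfg.max_rejections:
                raise GenerationError(
                    f"exceeded {cfg.max_rejections} rejected growth attempts; "
                    "fewer reticulations may be needed at this size"
                )


def _grow_once(cfg: GeneratorConfig, tree_child: bool, rng: random.Random) -> PhyloNetwork:
    import networkx as nx

    g = nx.DiGraph()
    g.add_node(0)
    next_id = 1
    leaves = [0]
    cherries_left = cfg.num_leaves - 1
    rets_left = cfg.num_reticulations

    def fresh() -> int:
        nonlocal next_id
        v = next_id
        next_id += 1
        return v

    while cherries_left or rets_left:
        can_ret = rets_left > 0 and len(leaves) >= 2
        if can_ret and cherries_left > 0:
            do_ret = rng.random() < rets_left / (rets_left + cherries_left)
        elif can_ret:
            do_ret = True
        elif cherries_left > 0:
            do_ret = False
        else:
            raise GenerationError(
                "cannot place a reticulated cherry on fewer than two leaves; "
                "reduce num_reticulations or increase num_leaves"
            )
        if not do_ret:
            # inverse cherry: a leaf becomes the parent of two new leaves
            u = leaves.pop(rng.randrange(len(leaves)))
            a, b = fresh(), fresh()
            g.add_edge(u, a)
            g.add_edge(u, b)
            leaves.extend((a, b))
            cherries_left -= 1
            continue
        # inverse reticulated cherry on an ordered leaf pair (u, h):
        # u -> h turns h into a reticulation; u and h each get a new leaf
        if tree_child:
            # the only node whose tree-child status is at risk is h's
            # parent, which loses h as a tree child
            def safe(hh) -> bool:
                (p,) = g.predecessors(hh)
                others = [c for c in g.successors(p) if c != hh]
                return any(g.in_degree(c) <= 1 for c in others)

            candidates = [hh for hh in leaves if safe(hh)]
        else:
            candidates = leaves
        if not candidates:
            # no leaf can become a reticulation without breaking the
            # tree-child condition; grow a cherry first to create one,
            # or restart the whole growth if cherries ran out
            if cherries_left == 0:
                raise _Stuck
            u = leaves.pop(rng.randrange(len(leaves)))
            a, b = fresh(), fresh()
            g.add_edge(u, a)
            g.add_edge(u, b)
            leaves.extend((a, b))
            cherries_left -= 1
            continue
        h = candidates[rng.randrange(len(candidates))]
        others_u = [x for x in leaves if x != h]
        u = others_u[rng.randrange(len(others_u))]
        iu, ih = leaves.index(u), leaves.index(h)
        a, b = fresh(), fresh()
        g.add_edge(u, a)
        g.add_edge(u, h)
        g.add_edge(h, b)
        for idx in sorted((iu, ih), reverse=True):
            leaves.pop(idx)
        leaves.extend((a, b))
        rets_left -= 1

    labels = {v: f"t{i + 1}" for i, v in enumerate(sorted(leaves))}
    return PhyloNetwork(
        edges=g.edges, leaf_labels=labels, nodes=g.nodes, root=0
    )


def generate_random_tree_child(cfg: GeneratorConfig) -> PhyloNetwork:
    """A random pristine binary tree-child network, orchard by construction."""
    return _grow(cfg, tree_child=True)


def generate_random_orchard(cfg: GeneratorConfig) -> PhyloNetwork:
    """A random pristine binary orchard network, not necessarily tree-child."""
    return _grow(cfg, tree_child=False)


# -- explicit clique-minor family ---------------------------------------------


def build_clique_minor_network(n: int) -> tuple[PhyloNetwork, MinorSpec]:
    """The explicit tree-child network with a K_n minor, and its witness.

    Nodes are u_{a,b} (1 <= a < b <= n), reticulations h_{a,b}
    (2 <= a < b <= n), splitters v_{a,b} with pendant leaves x_{a,b}
    (2 <= a < b−1, b <= n), and leaves z_1..z_n; the root is u_{1,2}.  Row
    a follows the path u_{a,a+1} … u_{a,n} z_a, rows 3..n are entered
    through chains of reticulations h_{2,b} v_{2,b} … h_{b−1,b}, and the
    cross edges u_{a,b} -> h_{a,b} (plus u_{1,b} -> h_{2,b} and
    u_{1,2} -> u_{2,3}) realize every pair adjacency.  Contracting the n
    disjoint row/chain paths (after dropping the pendant x leaves) yields
    K_n; the (n−1)(n−2)/2 reticulations all sit in one blob, so the level
    meets the clique bound exactly.
    """
    if n < 3:
        raise ValueError("the clique-minor construction needs n >= 3")

    names: dict[str, int] = {}

    def node(name: str) -> int:
        if name not in names:
            names[name] = len(names)
        return names[name]

    def u(a, b):
        return node(f"u_{a}_{b}")

    def h(a, b):
        return node(f"h_{a}_{b}")

    def v(a, b):
        return node(f"v_{a}_{b}")

    def x(a, b):
        return node(f"x_{a}_{b}")

    def z(a):
        return node(f"z_{a}")

    edges: list[tuple[int, int]] = []

    # rows 1 and 2: plain directed paths ending in z_1, z_2
    for a in (1, 2):
        for l in range(a + 1, n):
            edges.append((u(a, l), u(a, l + 1)))
        edges.append((u(a, n), z(a)))
    # rows 3..n−1: reticulation/splitter chain, then the u path
    for b in range(3, n):
        for a in range(2, b - 1):
            edges.append((h(a, b), v(a, b)))
            edges.append((v(a, b), x(a, b)))
            edges.append((v(a, b), h(a + 1, b)))
        edges.append((h(b - 1, b), u(b, b + 1)))
        for l in range(b + 1, n):
            edges.append((u(b, l), u(b, l + 1)))
        edges.append((u(b, n), z(b)))
    # row n: chain ends directly in z_n
    for a in range(2, n - 1):
        edges.append((h(a, n), v(a, n)))
        edges.append((v(a, n), x(a, n)))
        edges.append((v(a, n), h(a + 1, n)))
    edges.append((h(n - 1, n), z(n)))
    # cross edges realizing the clique adjacencies
    for b in range(3, n + 1):
        edges.append((u(1, b), h(2, b)))
    for a in range(2, n + 1):
        for b in range(a + 1, n + 1):
            edges.append((u(a, b), h(a, b)))
    edges.append((u(1, 2), u(2, 3)))

    labels = {z(a): f"z_{a}" for a in range(1, n + 1)}
    labels.update(
        {x(a, b): f"x_{a}_{b}" for b in range(4, n + 1) for a in range(2, b - 1)}
    )
    net = PhyloNetwork(
        edges=edges,
        leaf_labels=labels,
        root=u(1, 2),
        nodes=range(len(names)),
        node_names={i: nm for nm, i in names.items()},
    )

    classes: dict[str, set] = {}
    classes["z_1"] = {u(1, b) for b in range(2, n + 1)} | {z(1)}
    classes["z_2"] = {u(2, b) for b in range(3, n + 1)} | {z(2)}
    for b in range(3, n):
        members = {h(a, b) for a in range(2, b)}
        members |= {v(a, b) for a in range(2, b - 1)}
        members |= {u(b, l) for l in range(b + 1, n + 1)}
        members.add(z(b))
        classes[f"z_{b}"] = members
    last = {h(a, n) for a in range(2, n)} | {v(a, n) for a in range(2, n - 1)}
    last.add(z(n))
    classes[f"z_{n}"] = last

    spec = MinorSpec.make(
        classes,
        [(f"z_{a}", f"z_{b}") for a, b in combinations(range(1, n + 1), 2)],
    )
    return net, spec
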