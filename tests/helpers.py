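"""Seeded random factories shared across test modules."""

import random

import networkx as nx

from cherrycount import GeneratorConfig, Poset, generate_random_tree_child


def random_poset(rng: random.Random, n: int, density: float = 0.35) -> Poset:
    """A random poset on 0..n−1: each pair i<j related with prob ``density``."""
    pairs = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < density
    ]
    return Poset(range(n), pairs)


def random_tree_poset(rng: random.Random, n: int) -> Poset:
    """A random forest poset: most elements cover exactly one smaller one."""
    pairs = []
    for j in range(1, n):
        if rng.random() < 0.9:  # occasional extra roots: forests, not just trees
            pairs.append((rng.randrange(j), j))
    return Poset(range(n), pairs)


def tree_child_sample(count: int, seed: int, max_leaves: int = 7, max_retics: int = 3):
    """A reproducible stream of small random tree-child networks."""
    rng = random.Random(seed)
    nets = []
    for i in range(count):
        leaves = rng.randint(2, max_leaves)
        retics = rng.randint(0, min(max_retics, leaves - 1))
        nets.append(
            generate_random_tree_child(
                GeneratorConfig(num_leaves=leaves, num_reticulations=retics, seed=seed + i)
            )
        )
    return nets


def isomorphic(N, M, match_labels: bool = True) -> bool:
    """Digraph isomorphism, by default requiring leaf labels to agree."""
    g1, g2 = N.graph.copy(), M.graph.copy()
    if match_labels:
        for g, net in ((g1, N), (g2, M)):
            for v in g:
                g.nodes[v]["label"] = net.leaf_labels.get(v)
        return nx.is_isomorphic(
            g1, g2, node_match=lambda a, b: a.get("label") == b.get("label")
        )
    return nx.is_isomorphic(g1, g2)
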