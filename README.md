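# cherrycount

Exact counting of **cherry reduction sequences** in binary tree-child
phylogenetic networks, by reduction to counting **linear extensions** of a
poset.

## The problem

A rooted binary phylogenetic network represents the evolutionary history of
a set of taxa Σ: leaves are taxa, internal tree nodes are speciations, and
*reticulations* (nodes with two incoming edges) are hybridization or
horizontal-transfer events.  Orchard networks — a biologically relevant
class that contains all tree-child networks — can be dismantled step by
step the way trees can: at each step one removes a *cherry* (two leaves
with a common parent) or a *reticulated cherry* (a leaf whose sibling is a
reticulation whose only child is a leaf).  The number of distinct complete
dismantling orders, |CR-Seq(N)|, is a topological signature of the network,
much as the number of linear extensions is for a poset — and for tree-child
networks the two notions coincide exactly:

> |CR-Seq(N)| = |LinExt(T(N̊))|,

where T(N̊) is the set of internal tree nodes ordered by reachability
(u ≼ v iff a directed path u ⇝ v exists).  Recording which node is reduced
at each step maps a sequence to a permutation of T(N̊) listing maximal
elements first; reversing it gives a linear extension of T(N̊), and for
tree-child networks every linear extension arises this way (terminal nodes
are exactly the maximal elements of the poset).  Beyond tree-child the map
is only injective: some maximal internal tree node may start no reduction
sequence, so |CR-Seq(N)| ≤ |LinExt(T(N̊)^op)| can be strict.

The package is aimed at people working on the combinatorics of phylogenetic
networks: it provides the network model (pristine and mid-reduction), the
reduction calculus, the poset machinery, exact big-integer linear-extension
counters, random and explicit network generators, and level/tree-width
bound formulas.

## What is implemented

- **Networks** (`cherrycount.network`, `cherrycount.io`): validated rooted
  binary networks with stable integer node identifiers; extended Newick
  (`#Hk` hybrid tags) and TSV edge-list I/O; blob decomposition and level;
  the tree-width upper bounds tw(N) ≤ level + 1 ≤ reticulations + 1.
- **Reductions** (`cherrycount.reduction`): terminal-node detection, the
  CR(N, u) operation (returning a literal subnetwork), orchard recognition,
  exhaustive sequence enumeration, and the sequence ↔ extension maps.
- **Posets** (`cherrycount.poset`): reachability posets, order-duals, a
  definitional transitive-reduction oracle, and the fast Hasse-diagram
  construction for tree-child networks by leaf removal and contraction of
  every reticulation into its tree-node child (a minor of N, which is what
  bounds its tree-width by the level of the network).
- **Counting** (`cherrycount.lecount`): O(2^p·p) dynamic programming over
  downset bitmasks, comparability-component decomposition with multinomial
  recombination, a hook-length closed form for forest posets, a brute-force
  oracle, and `count_cherry_sequences`, the headline operation.
- **Generators & bounds** (`cherrycount.generate`, `cherrycount.minors`):
  seeded random tree-child / orchard networks grown by inverse reductions;
  the explicit family of tree-child networks with a K_n minor and level
  (n−1)(n−2)/2 (showing tree-child networks have unbounded tree-width);
  minor verification and the level lower bound |E(H)| − |V(H)| + 1 from any
  biconnected minor H, with the clique and grid specializations.

All counts are exact integers; there is no floating point on any counting
path.

## Worked example

The smallest reticulated tree-child network — a root whose two children
both form reticulated cherries through a shared reticulation — in the
extended Newick dialect:

```sh
$ echo '((a,(h)#H1)u1,(#H1,b)u2)r;' > demo.nwk
$ cherrycount count --input demo.nwk --json
cherrycount 0.1.0: read demo.nwk (enewick), 7 nodes
p=|T(N̊)|=3 r=1 level=1 tw<=min(2,2) method=lecount
{"count": "2", "p": 3, "r": 1, "level": 1, "tw_upper": 2, "method": "lecount"}
```

The diagnostics (stderr) say the network has p = 3 internal tree nodes,
r = 1 reticulation, level 1, and tree-width at most 2; the count (stdout)
says exactly 2 dismantling orders exist.  They can be listed:

```sh
$ cherrycount enumerate --input demo.nwk --quiet
u1,u2,r
u2,u1,r
```

Either reticulated cherry may be reduced first; the root is always last.
Reversed, these are precisely the 2 linear extensions of the poset
r ≺ u1, r ≺ u2.  The same computation from Python, on a larger random
network:

```python
from cherrycount import (GeneratorConfig, generate_random_tree_child,
                         count_cherry_sequences, internal_tree_nodes, level)

N = generate_random_tree_child(
    GeneratorConfig(num_leaves=7, num_reticulations=3, seed=11))
print("p =", len(internal_tree_nodes(N)), " level =", level(N),
      " sequences =", count_cherry_sequences(N))
# p = 9  level = 3  sequences = 4
```

Other subcommands: `validate` (structure report, tree-child/orchard flags,
level, tree-width bounds), `cover-graph` (the Hasse diagram of T(N̊) and
the contraction map), `generate` (random networks, plain trees, or the
clique-minor family, e.g. `--type clique-minor --n 4`).

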