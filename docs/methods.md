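# Methods

## Model and scope

The objects are rooted binary phylogenetic networks on a taxon set Σ:
directed acyclic graphs with a single in-degree-0 root reaching every node,
in which every node of in-degree ≥ 2 (a reticulation) has out-degree 1,
every non-root internal node has degrees (in, out) ∈ {(1,2), (2,1)}, the
root has (0, 2) (unless the network is a single node), and leaves
(out-degree 0) are bijectively labeled by Σ.  Non-binary and unrooted
networks are out of scope; branch lengths are parsed and ignored.

Two validation regimes coexist in one type.  *Pristine* networks satisfy
the full definition.  *Reduced* networks are the intermediate stages of a
dismantling: cherry reductions create unlabeled leaves (the reduced node
itself, and any reticulation that lost a parent and its out-edge), so label
bijectivity and the no-elementary-node rule are deliberately not enforced
there; the admissible degree patterns are exactly those reachable by
reductions, {(0,0), (0,2), (1,0), (1,2), (2,1)}.  Node roles are always a
function of *current* degrees — an ex-reticulation of in-degree 1 is a tree
node from then on — with reticulation (in-degree ≥ 2) taking precedence
over the leaf test, then leaf over root.

Node identifiers are opaque integers fixed at construction and never
renumbered: a reduction returns a literal subnetwork (its nodes and edges
are nodes and edges of the input), so a node keeps its identity along a
whole reduction sequence.  This is what lets sequences be compared with
linear extensions element-by-element.

## The reduction calculus

A terminal node roots a cherry (two leaf children) or a reticulated cherry
(a leaf child, plus a reticulation child whose single child is a leaf).
CR(N, u) removes every edge whose tail is a weak descendant of u and every
strict descendant of u that is currently a tree node; a descendant
reticulation survives on its remaining in-edge as a new leaf.  After each
reduction the internal tree nodes satisfy T(N̊) = T(N̊′) ∪ {u}, so every
complete sequence has length |T(N̊)| and ends at the root.

Orchard recognition is greedy: reduce any terminal node until none remains.
Greediness is decisive because all complete sequences of a network have
equal length; a greedy dead end above one node therefore certifies that no
sequence exists at all.  Exhaustive enumeration tries terminal nodes in
ascending identifier order at every step (reproducible output) and is
guarded at |T(N̊)| ≤ 10 by default — the worst case is factorial — with
counting available far beyond that.

For tree-child networks the terminal nodes are exactly the maximal elements
of the reachability poset on T(N̊), which makes the map
(sequence ↦ its own node order) a bijection onto the linear extensions of
the dual poset, and (sequence ↦ reversed order) a bijection onto
LinExt(T(N̊)).  For general orchard networks only injectivity survives: a
maximal internal tree node need not be terminal (both its children can be
reticulations), so the sequence count can be strictly below the extension
count.  The test suite pins an 11-node example of this, and the random
orchard generator (tree-child rejection disabled) finds such networks
routinely.

## Hasse diagram by contraction

For a pristine binary tree-child network the Hasse diagram of T(N̊) can be
built without any reachability computation: drop the leaves, drop every
reticulation whose only child was a leaf, and contract each surviving
reticulation into its child (tree-child guarantees the child is a tree
node).  The quotient map assigns indices to internal tree nodes in
ascending identifier order and sends discarded nodes to the sentinel −1;
classes have size 1 or 2, and every 2-class is a {reticulation, tree-child}
pair joined by a network edge, so the output is a minor of N — whence
tw(cover graph) ≤ tw(N) ≤ level(N) + 1.

One correction to the naive construction was needed.  When the two parents
of a reticulation are comparable through tree nodes (u feeds both a
reticulation h above v and, through its other child, h's other parent), the
contracted DAG contains the transitive shortcut [u] → [v] alongside a
longer directed path, so it is a strict supergraph of the Hasse diagram
with the same reachability closure.  The closure — and therefore every
count — is unaffected, but since this function promises the Hasse diagram,
it finishes with a transitive reduction of the (small) contracted DAG.
Edge deletion keeps the result a minor, so the tree-width argument is
unchanged.  A unit test pins the minimal 7-node network exhibiting the
shortcut.

## Counting linear extensions

Counts are exact arbitrary-precision integers throughout; they exceed 64
bits already for modest antichains.

- **Brute force** (≤ 8 elements): filter all |X|! permutations.  This is
  the oracle everything else is checked against.
- **Downset DP** (default cap 28 elements): e(∅) = 1 and
  e(D) = Σ_{m maximal in D} e(D ∖ {m}), answering e(X).  Downsets are
  bitmasks over elements in ascending identifier order; maximality in D is
  one AND against a precomputed strictly-above mask.  Memoization is lazy,
  so memory tracks the number of *reachable* downsets (the downset lattice)
  rather than 2^p — narrow posets stay cheap.  Removing maximal elements
  builds extensions right-to-left; the minimal-first direction is
  equivalent by duality, and duality invariance (LE(P) = LE(P^op)) is
  tested.
- **Component decomposition**: elements in different comparability
  components are mutually incomparable, so the total count is the product
  of component counts times the multinomial coefficient of the component
  sizes.  This is the default entry point.
- **Forest closed form**: when the Hasse diagram is a forest with edges
  away from the roots, LE(P) = n!/∏_v s(v) with s(v) the size of v's
  up-set including v.  Used purely as an independent cross-check of the DP
  on tree-shaped posets; not part of the main path.

`count_cherry_sequences` composes the pieces: single node → 1; tree-child
networks → contraction, closure, component DP (counting LinExt(T(N̊)),
which equals the sequence count); otherwise brute-force enumeration under
the guard, with a warning and count 0 for non-orchard inputs.  The `auto`
method chooses per the tree-child test.

## Generators

The random generator grows a network from one node by reversing reductions:
an inverse cherry turns a leaf into the parent of two new leaves, and an
inverse reticulated cherry turns an ordered leaf pair (u, h) into
u → {new leaf, h}, h → new leaf, making h a reticulation.  Growth is the
reverse of a reduction sequence, so every output is orchard by
construction.  In tree-child mode the only node whose tree-child status a
reticulation move can break is h's parent, so moves are drawn from the
safe candidates directly; if no safe candidate exists the generator grows a
cherry first, and if cherries are exhausted it restarts the growth with the
advanced RNG state (deterministic in the seed, counted against a rejection
budget).  Leaves are labeled t1, t2, … in identifier order at the end.
Identical configurations yield byte-identical serializations.

Default study conditions in the tests and the acceptance script: 200
networks with 2–7 leaves and 0–3 reticulations (sizes where exhaustive
enumeration stays cheap, p = |Σ| + r − 1 ≤ 9), 50 searched orchard
non-tree-child networks at 5 leaves / 3 reticulations, 500 random posets of
at most 7 elements with pair density drawn from [0.1, 0.7], and 100 random
forest posets of at most 12 elements.  The random networks emulate
topology only — no branch lengths, no time-consistency, no inheritance
probabilities — and the generator is reproducible rather than uniform over
network space, so passing tests certify the combinatorial identities, not
distributional properties of real phylogenies.

The explicit clique-minor family realizes, for each n ≥ 3, a binary
tree-child network with (n−1)(n−2)/2 reticulations in a single blob whose
underlying graph has a K_n minor: n node-disjoint directed paths (two plain
rows, the rest entered through chains of reticulations) pairwise joined by
cross edges into the reticulations, contracted class-by-class to the
clique after the pendant splitter leaves are removed.  A K_n minor forces
tree-width ≥ n − 1, so tree-child networks have unbounded tree-width while
this family's level grows only quadratically — and here the biconnected
minor bound level ≥ |E| − |V| + 1 = (n−1)(n−2)/2 is tight.  The printed
edge list of the construction omits the root-to-second-row edge that its
own minor argument uses; the construction includes it (without it the
second row is unreachable and the root would have out-degree 1).

## Numerical and degenerate-input choices

- Level of a network with no nontrivial blob (any tree) is 0; blobs are
  biconnected components with ≥ 3 nodes, so bridges are never blobs and
  every blob contains a reticulation.
- |T(N̊)| is always computed from the graph; for pristine binary networks
  it equals |Σ| + r − 1 (degree-sum argument), which is the identity the
  tests assert.
- The single-node network is valid ("the root is a leaf"), has N̊ = ∅, one
  (empty) reduction sequence, and count 1.
- The enumeration guard (10) and DP cap (28) are resource guards, not
  tolerances; exceeding them raises a typed error naming the alternative.
- The eNewick writer expands each reticulation under its first-visited
  parent and emits `#Hk` references elsewhere; round-trips preserve leaf
  labels exactly and topology up to node renumbering.

## Known limitations

- Counting is exact and exponential-state: posets beyond the DP cap need
  the (not implemented) tree-decomposition counting algorithm or
  randomized approximation, both out of scope here.
- The generator does not sample uniformly from tree-child network space;
  conclusions about "random networks" mean *this* growth process.
- Reconstruction of networks from sequences (cherry *picking*) is not
  implemented; growth is used internally by the generator only.
- Exact tree-width is never computed — only the level/reticulation upper
  bounds and minor-based lower bounds are reported.
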