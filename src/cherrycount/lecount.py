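"""Exact counting of linear extensions, and the headline cherry-sequence count.

A linear extension of a poset (X, ≼) is a total order compatible with ≼;
counting them is #P-complete in general, but exact counting is practical at
the sizes phylogenetic networks induce.  Four counters are provided:

* :func:`count_linext_bruteforce` — permutation filter, the oracle (|X| ≤ 8);
* :func:`count_linext_downset_dp` — O(2^p · p) dynamic programming over
  downsets encoded as bitmasks, memoizing only reachable downsets;
* :func:`count_linext` — front door: splits into comparability components
  and combines the per-component DP counts with a multinomial shuffle;
* :func:`count_linext_forest_closedform` — the hook-length closed form
  n!/∏ subtree sizes for posets whose Hasse diagram is a forest, used as
  an independent cross-check.

:func:`count_cherry_sequences` counts the cherry reduction sequences of a
binary tree-child network by counting the linear extensions of the
reachability poset on its internal tree nodes T(N̊): the two sets are in
bijection (reverse the sequence), and dualizing preserves the count.  All
counts are exact Python integers — they overflow 64 bits quickly.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

from .network import NetworkError, PhyloNetwork, internal_tree_nodes, is_tree_child
from .poset import (
    Poset,
    cover_graph_by_contraction,
    poset_from_cover_graph,
    transitive_reduction_oracle,
)
from .reduction import enumerate_cr_sequences

__all__ = [
    "count_linext_bruteforce",
    "count_linext_downset_dp",
    "count_linext",
    "count_linext_forest_closedform",
    "count_cherry_sequences",
    "CountingCapError",
]

BRUTEFORCE_CAP = 8
DEFAULT_DP_CAP = 28


class CountingCapError(ValueError):
    """A size guard on a counting routine was exceeded."""


def count_linext_bruteforce(P: Poset) -> int:
    """Count extensions by checking every permutation; oracle for the DP."""
    n = len(P)
    if n > BRUTEFORCE_CAP:
        raise CountingCapError(
            f"brute force is capped at {BRUTEFORCE_CAP} elements, got {n}"
        )
    pairs = P.strict_pairs()
    count = 0
    for perm in permutations(P.elements):
        pos = {x: i for i, x in enumerate(perm)}
        if all(pos[x] < pos[y] for (x, y) in pairs):
            count += 1
    return count


def count_linext_downset_dp(P: Poset, cap: int = DEFAULT_DP_CAP) -> int:
    """Count extensions by dynamic programming over downsets.

    With e(∅) = 1 and e(D) = Σ over maximal elements m of the downset D of
    e(D \\ {m}), the answer is e(X): stripping maximal elements one at a
    time builds the extension right to left.  Downsets are bitmasks over
    the elements in ascending order; memoization touches only reachable
    downsets, so memory tracks the actual downset lattice rather than 2^p
    for narrow posets.
    """
    n = len(P)
    if n > cap:
        raise CountingCapError(
            f"downset DP capped at {cap} elements, got {n}; "
            "decompose the poset or raise the cap"
        )
    if n == 0:
        return 1
    elems = P.elements
    index = {x: i for i, x in enumerate(elems)}
    above = [0] * n  # bitmask of elements strictly above i
    for i, x in enumerate(elems):
        for y in P.strictly_above(x):
            above[i] |= 1 << index[y]

    memo: dict[int, int] = {0: 1}
    full = (1 << n) - 1

    def e(mask: int) -> int:
        cached = memo.get(mask)
        if cached is not None:
            return cached
        total = 0
        m = mask
        while m:
            bit = m & -m
            i = bit.bit_length() - 1
            # i is maximal in the downset iff nothing above it is present
            if not (above[i] & mask):
                total += e(mask ^ bit)
            m ^= bit
        memo[mask] = total
        return total

    # iterative in effect: recursion depth is at most n (≤ cap)
    return e(full)


def count_linext(P: Poset, cap: int = DEFAULT_DP_CAP) -> int:
    """Count linear extensions exactly, decomposing by comparability.

    Elements in different comparability components are mutually
    incomparable, so extensions of the whole poset are shuffles of
    per-component extensions: multiply the component counts by the
    multinomial coefficient of the component sizes.
    """
    components = P.comparability_components()
    total_count = 1
    remaining = len(P)
    for comp in components:
        sub = P.restrict(comp)
        total_count *= count_linext_downset_dp(sub, cap=cap)
        total_count *= math.comb(remaining, len(comp))
        remaining -= len(comp)
    return total_count


def count_linext_forest_closedform(P: Poset) -> int:
    """Hook-length closed form for forest posets: n! / ∏_v |up-set of v|.

    Applies when the Hasse diagram is a forest with edges pointing away
    from the roots, i.e. every element covers at most one other element;
    then the strict up-set of v together with v is its "subtree" and the
    count is n! divided by the product of subtree sizes.
    """
    cover = transitive_reduction_oracle(P)
    in_deg: dict = {x: 0 for x in P.elements}
    for _, y in cover.edges:
        in_deg[y] += 1
    if any(d > 1 for d in in_deg.values()):
        raise ValueError(
            "closed form requires a forest-shaped Hasse diagram "
            "(some element covers two incomparable elements)"
        )
    n = len(P)
    result = math.factorial(n)
    for x in P.elements:
        result, rem = divmod(result, len(P.strictly_above(x)) + 1)
        assert rem == 0, "hook product must divide n! on a forest poset"
    return result


def count_cherry_sequences(
    N: PhyloNetwork, method: str = "auto", guard: int = 10, cap: int = DEFAULT_DP_CAP
) -> int:
    """Number of cherry reduction sequences of a network.

    ``lecount`` builds the Hasse diagram of the reachability poset on
    T(N̊) by leaf removal and reticulation contraction, reconstructs the
    poset, and counts its linear extensions — valid for tree-child
    networks, where reduction sequences biject with linear extensions.
    ``bruteforce`` enumerates the sequences directly (any orchard network,
    guarded).  ``auto`` picks ``lecount`` when the network is tree-child
    and falls back to brute force otherwise.
    """
    if method not in ("auto", "lecount", "bruteforce"):
        raise ValueError(f"unknown method {method!r}")
    if N.is_single_node():
        return 1  # the empty sequence
    if method == "auto":
        method = "lecount" if is_tree_child(N) else "bruteforce"
    if method == "lecount":
        if not is_tree_child(N):
            raise NetworkError(
                "the linear-extension count equals the sequence count only "
                "for tree-child networks; in a general orchard network a "
                "maximal internal tree node may start no reduction sequence "
                "— use method='bruteforce'"
            )
        cover, _ = cover_graph_by_contraction(N)
        return count_linext(poset_from_cover_graph(cover), cap=cap)
    sequences = enumerate_cr_sequences(N, max_nodes=guard)
    if not sequences:
        warnings.warn(
            "network is not orchard: no cherry reduction sequence exists",
            stacklevel=2,
        )
        return 0
    return len(sequences)
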