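"""Cherry reductions: terminal detection, CR, orchard test, enumeration,
and the sequence ↔ linear-extension correspondence."""

import pytest

from cherrycount import (
    CRSequence,
    ReductionError,
    TerminalKind,
    cherry_reduce,
    crseq_to_linext,
    dualize,
    enumerate_cr_sequences,
    internal_tree_nodes,
    is_orchard,
    is_tree_child,
    linext_to_crseq,
    reachability_poset,
    replay,
    terminal_nodes,
    validate,
)
from helpers import tree_child_sample


class TestTerminalNodes:
    def test_cherry_network(self, cherry):
        assert terminal_nodes(cherry) == {0: TerminalKind.CHERRY}

    def test_reticulated_fixture(self, minimal_reticulated):
        assert terminal_nodes(minimal_reticulated) == {
            1: TerminalKind.RETICULATED_CHERRY,
            2: TerminalKind.RETICULATED_CHERRY,
        }

    def test_balanced_tree(self, balanced_tree):
        assert terminal_nodes(balanced_tree) == {
            1: TerminalKind.CHERRY,
            2: TerminalKind.CHERRY,
        }

    def test_star_has_none(self, star):
        assert terminal_nodes(star) == {}

    def test_reticulation_with_internal_child_blocks(self, contracted_pair_network):
        # h's child w is internal, so u1/u2 root no reticulated cherry yet
        assert set(terminal_nodes(contracted_pair_network)) == {6}


class TestCherryReduce:
    def test_cherry_case(self):
        from cherrycount import PhyloNetwork

        N = PhyloNetwork(
            edges=[(0, 1), (0, 2), (1, 3), (1, 4)],
            leaf_labels={2: "c", 3: "a", 4: "b"},
        )
        M = cherry_reduce(N, 1)
        assert set(M.nodes()) == {0, 1, 2}
        assert set(M.edges()) == {(0, 1), (0, 2)}
        assert M.out_degree(1) == 0  # u became a leaf

    def test_reticulated_cherry_case(self, minimal_reticulated):
        M = cherry_reduce(minimal_reticulated, 1)
        # l1 (4) and l3 (6) removed; u1 and the ex-reticulation are leaves
        assert 4 not in M and 6 not in M
        assert M.out_degree(1) == 0
        assert M.in_degree(3) == 1 and M.out_degree(3) == 0
        assert (2, 3) in M.edges()
        assert validate(M, "reduced") == []

    def test_non_terminal_raises(self, minimal_reticulated):
        with pytest.raises(ReductionError, match="cherry"):
            cherry_reduce(minimal_reticulated, 0)

    def test_unknown_node_raises(self, cherry):
        with pytest.raises(KeyError):
            cherry_reduce(cherry, 42)

    def test_identifiers_are_preserved(self, minimal_reticulated):
        M = cherry_reduce(minimal_reticulated, 2)
        assert set(M.nodes()) <= set(minimal_reticulated.nodes())
        assert set(M.edges()) <= set(minimal_reticulated.edges())


class TestIsOrchard:
    def test_trees_are_orchard(self, balanced_tree):
        assert is_orchard(balanced_tree)

    def test_tree_child_networks_are_orchard(self):
        for N in tree_child_sample(20, seed=41):
            assert is_orchard(N)

    def test_stuck_network_is_not_orchard(self, non_orchard):
        assert validate(non_orchard) == []
        assert not is_orchard(non_orchard)
        assert enumerate_cr_sequences(non_orchard) == []


class TestEnumerate:
    def test_star_has_one_empty_sequence(self, star):
        assert enumerate_cr_sequences(star) == [CRSequence(())]

    def test_balanced_tree_has_two(self, balanced_tree):
        seqs = enumerate_cr_sequences(balanced_tree)
        assert [s.reduced_nodes for s in seqs] == [(1, 2, 0), (2, 1, 0)]

    def test_reticulated_fixture_has_two(self, minimal_reticulated):
        seqs = enumerate_cr_sequences(minimal_reticulated)
        assert [s.reduced_nodes for s in seqs] == [(1, 2, 0), (2, 1, 0)]

    def test_guard(self, balanced_tree):
        with pytest.raises(ReductionError, match="guard"):
            enumerate_cr_sequences(balanced_tree, max_nodes=2)

    def test_all_sequences_have_length_T(self):
        for N in tree_child_sample(15, seed=43):
            p = len(internal_tree_nodes(N))
            seqs = enumerate_cr_sequences(N)
            assert seqs and all(len(s) == p for s in seqs)
            # last reduced node is always the root
            assert all(s.reduced_nodes[-1] == N.root for s in seqs)

    def test_shrinking_invariant_each_step(self):
        # T(N̊) = T(N̊') ∪ {u} and u is a leaf of N' after every reduction
        for N in tree_child_sample(10, seed=47):
            for seq in enumerate_cr_sequences(N)[:3]:
                cur = N
                for u in seq:
                    before = internal_tree_nodes(cur)
                    cur = cherry_reduce(cur, u)
                    after = internal_tree_nodes(cur)
                    assert before == after | {u}
                    assert cur.out_degree(u) == 0

    def test_tree_child_preserved_each_step(self):
        for N in tree_child_sample(10, seed=53):
            seq = enumerate_cr_sequences(N)[0]
            for M in replay(N, seq.reduced_nodes):
                assert is_tree_child(M)


class TestSequenceExtensionMaps:
    def test_reversal_is_linear_extension(self, minimal_reticulated):
        seqs = enumerate_cr_sequences(minimal_reticulated)
        P = reachability_poset(minimal_reticulated)
        for s in seqs:
            pi = crseq_to_linext(minimal_reticulated, s)
            assert pi == tuple(reversed(s.reduced_nodes))
            assert P.is_linear_extension(pi)

    def test_length_one_sequence(self, cherry):
        (s,) = enumerate_cr_sequences(cherry)
        assert crseq_to_linext(cherry, s) == (0,)

    def test_invalid_sequence_replay_error(self, minimal_reticulated):
        with pytest.raises(ReductionError, match="step 0"):
            crseq_to_linext(minimal_reticulated, CRSequence((0, 1, 2)))

    def test_incomplete_sequence_rejected(self, minimal_reticulated):
        with pytest.raises(ReductionError, match="incomplete"):
            crseq_to_linext(minimal_reticulated, CRSequence((1,)))

    def test_round_trip_identity(self):
        for N in tree_child_sample(10, seed=59):
            for s in enumerate_cr_sequences(N)[:5]:
                pi = crseq_to_linext(N, s)
                assert linext_to_crseq(N, reversed(pi)) == s

    def test_dual_extension_replays(self, minimal_reticulated):
        s = linext_to_crseq(minimal_reticulated, (2, 1, 0))
        assert s.reduced_nodes == (2, 1, 0)

    def test_order_violation_named(self, minimal_reticulated):
        # the root is the minimum, so it cannot be reduced first
        with pytest.raises(ReductionError, match="dual"):
            linext_to_crseq(minimal_reticulated, (0, 1, 2))

    def test_non_tree_child_rejected(self, orchard_not_tree_child):
        assert is_orchard(orchard_not_tree_child)
        with pytest.raises(ReductionError, match="tree-child"):
            linext_to_crseq(orchard_not_tree_child, (1, 5, 6, 2, 0))


class TestMaximalElementsCorrespondence:
    def test_terminal_iff_maximal_for_tree_child(self):
        for N in tree_child_sample(200, seed=61):
            P = reachability_poset(N)
            assert set(terminal_nodes(N)) == P.maximal_elements()

    def test_fails_beyond_tree_child(self, orchard_not_tree_child):
        N = orchard_not_tree_child
        P = reachability_poset(N)
        assert set(terminal_nodes(N)) != P.maximal_elements()

    def test_sequences_are_dual_extensions_even_beyond_tree_child(
        self, orchard_not_tree_child
    ):
        # the sequence → dual-extension map is injective for any orchard
        # network, so the sequence count is bounded by the extension count
        N = orchard_not_tree_child
        dual = dualize(reachability_poset(N))
        seqs = enumerate_cr_sequences(N)
        orders = {s.reduced_nodes for s in seqs}
        assert len(orders) == len(seqs)
        assert all(dual.is_linear_extension(o) for o in orders)
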