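"""Network model: roles, validation, tree-child test, blobs, level, I/O."""

import random

import networkx as nx
import pytest

from cherrycount import (
    GeneratorConfig,
    NetworkError,
    NodeRole,
    ParseError,
    PhyloNetwork,
    blobs,
    build_clique_minor_network,
    cherry_reduce,
    classify_node,
    generate_random_tree_child,
    internal_tree_nodes,
    is_tree_child,
    level,
    parse_edgelist,
    parse_enewick,
    read_network,
    strip_leaves,
    treewidth_upper_bound,
    validate,
    write_edgelist,
    write_enewick,
    write_network,
)
from helpers import isomorphic, tree_child_sample


class TestClassifyNode:
    def test_roles_on_reticulated_fixture(self, minimal_reticulated):
        N = minimal_reticulated
        assert classify_node(N, 0) is NodeRole.ROOT
        assert classify_node(N, 1) is NodeRole.INTERNAL_TREE
        assert classify_node(N, 3) is NodeRole.RETICULATION
        assert classify_node(N, 6) is NodeRole.LEAF

    def test_ex_reticulation_becomes_leaf(self, minimal_reticulated):
        # after reducing u1, the reticulation has in-degree 1 / out-degree 0
        reduced = cherry_reduce(minimal_reticulated, 1)
        assert classify_node(reduced, 3) is NodeRole.LEAF

    def test_unknown_node(self, cherry):
        with pytest.raises(KeyError):
            classify_node(cherry, 99)

    def test_roles_partition_tree_vs_reticulation(self):
        # |T(N)| + |R(N)| = |V(N)| on every generated network
        for N in tree_child_sample(25, seed=11):
            tree = sum(
                1 for v in N.nodes()
                if classify_node(N, v) is not NodeRole.RETICULATION
            )
            assert tree + len(N.reticulations()) == len(N)


class TestValidate:
    def test_single_node_is_valid(self, star):
        assert validate(star, "pristine") == []

    def test_in2_out2_is_binary_violation(self):
        N = PhyloNetwork(
            edges=[(0, 1), (0, 2), (1, 3), (2, 3), (3, 4), (3, 5),
                   (1, 6), (2, 7)],
            leaf_labels={4: "a", 5: "b", 6: "c", 7: "d"},
        )
        assert any("degree" in line for line in validate(N, "pristine"))

    def test_two_roots_reported(self):
        N = PhyloNetwork(edges=[(0, 1), (0, 2)], nodes=[0, 1, 2, 3],
                         leaf_labels={1: "a", 2: "b", 3: "c"}, root=0)
        report = validate(N, "pristine")
        assert any("in-degree 0" in line for line in report)

    def test_elementary_node_reported_pristine_only(self):
        N = PhyloNetwork(edges=[(0, 1), (0, 2), (2, 3)],
                         leaf_labels={1: "a", 3: "b"})
        assert any("elementary" in line for line in validate(N, "pristine"))

    def test_unlabeled_and_duplicate_leaves(self):
        N = PhyloNetwork(edges=[(0, 1), (0, 2)], leaf_labels={1: "a"})
        assert any("unlabeled" in line for line in validate(N, "pristine"))
        M = PhyloNetwork(edges=[(0, 1), (0, 2)], leaf_labels={1: "a", 2: "a"})
        assert any("duplicate" in line for line in validate(M, "pristine"))

    def test_reduced_mode_accepts_reduction_output(self, minimal_reticulated):
        reduced = cherry_reduce(minimal_reticulated, 1)
        assert validate(reduced, "reduced") == []
        # but pristine mode flags the unlabeled new leaves
        assert validate(reduced, "pristine") != []

    def test_unknown_mode(self, cherry):
        with pytest.raises(ValueError):
            validate(cherry, "strict")


class TestTreeChild:
    def test_trees_are_tree_child(self, balanced_tree):
        assert is_tree_child(balanced_tree)

    def test_two_reticulation_children_is_not(self, orchard_not_tree_child):
        assert not is_tree_child(orchard_not_tree_child)

    def test_clique_family_is_tree_child(self):
        N, _ = build_clique_minor_network(4)
        assert is_tree_child(N)


class TestStripLeaves:
    def test_cherry_strips_to_root(self, cherry):
        g = strip_leaves(cherry)
        assert set(g.nodes) == {0} and g.number_of_edges() == 0

    def test_star_strips_to_empty(self, star):
        assert len(strip_leaves(star)) == 0

    def test_reticulated_fixture(self, minimal_reticulated):
        g = strip_leaves(minimal_reticulated)
        assert set(g.nodes) == {0, 1, 2, 3}
        assert g.number_of_edges() == 4

    def test_restripping_shrinks(self, minimal_reticulated):
        # (N̊)̊ ⊆ N̊: re-stripping removes only newly exposed sinks
        g1 = strip_leaves(minimal_reticulated)
        g2 = g1.subgraph([v for v in g1 if g1.out_degree(v) >= 1])
        assert set(g2.nodes) <= set(g1.nodes)


class TestBlobsAndLevel:
    def test_tree_has_level_zero(self, balanced_tree):
        assert blobs(balanced_tree) == [] and level(balanced_tree) == 0

    def test_reticulated_fixture_single_blob(self, minimal_reticulated):
        bs = blobs(minimal_reticulated)
        assert len(bs) == 1
        assert bs[0].nodes == frozenset({0, 1, 2, 3})
        assert bs[0].reticulation_count == 1
        assert level(minimal_reticulated) == 1

    def test_level_bounded_by_reticulations(self):
        for N in tree_child_sample(25, seed=23):
            assert level(N) <= len(N.reticulations())

    def test_nontrivial_blobs_have_a_reticulation(self):
        for N in tree_child_sample(25, seed=29):
            assert all(b.reticulation_count >= 1 for b in blobs(N))


class TestTreewidthUpperBound:
    @pytest.mark.parametrize(
        "k,r,expected", [(0, 0, (1, 1)), (1, 1, (2, 2)), (3, 5, (4, 6))]
    )
    def test_formula(self, k, r, expected):
        assert treewidth_upper_bound(k, r) == expected

    def test_level_cannot_exceed_reticulations(self):
        with pytest.raises(ValueError):
            treewidth_upper_bound(3, 2)


class TestIO:
    def test_plain_newick_tree(self):
        N = parse_enewick("((a,b)x,c)r;")
        assert len(N.leaves()) == 3
        assert len(internal_tree_nodes(N)) == 2
        assert validate(N) == []

    def test_reticulated_dialect(self, minimal_reticulated):
        N = parse_enewick("((a,(h)#H1)u1,(#H1,b)u2)r;")
        assert validate(N) == []
        assert isomorphic(N, minimal_reticulated, match_labels=False)

    def test_branch_lengths_parsed_and_ignored(self):
        N = parse_enewick("((a:0.1,b:0.2)x:0.3,c:1e-2)r;")
        assert sorted(N.leaf_labels.values()) == ["a", "b", "c"]

    @pytest.mark.parametrize(
        "bad", ["((a,b;", "(a,b))r;", "", "(a,b)r; x", "((a,a)u,b)r;",
                "((a,(h)#H1)u,b)r;"]
    )
    def test_malformed_inputs_raise(self, bad):
        with pytest.raises(ParseError):
            parse_enewick(bad)

    def test_hybrid_subtree_twice_raises(self):
        with pytest.raises(ParseError):
            parse_enewick("(((h)#H1,a)u,((h2)#H1,b)v)r;")

    def test_edgelist_round_trip(self, minimal_reticulated):
        text = write_edgelist(minimal_reticulated)
        M = parse_edgelist(text)
        assert isomorphic(minimal_reticulated, M)

    def test_edgelist_comments_and_names(self):
        text = "# a comment\nrho\tu\nrho\tv\nL\tu\talpha\nL\tv\tbeta\n"
        N = parse_edgelist(text)
        assert sorted(N.leaf_labels.values()) == ["alpha", "beta"]

    def test_read_network_from_path(self, tmp_path, balanced_tree):
        p = tmp_path / "net.nwk"
        p.write_text(write_enewick(balanced_tree))
        M = read_network(p, format="enewick")
        assert isomorphic(balanced_tree, M)

    def test_round_trip_100_random_networks(self):
        rng = random.Random(5)
        for i in range(100):
            leaves = rng.randint(2, 7)
            retics = rng.randint(0, min(3, leaves - 1))
            N = generate_random_tree_child(
                GeneratorConfig(num_leaves=leaves, num_reticulations=retics, seed=1000 + i)
            )
            for fmt in ("enewick", "edgelist"):
                M = read_network(write_network(N, fmt), format=fmt)
                assert isomorphic(N, M), (fmt, i)
                assert sorted(M.leaf_labels.values()) == sorted(
                    N.leaf_labels.values()
                )


class TestHandshake:
    def test_internal_tree_nodes_equal_leaves_plus_retics_minus_one(self):
        # degree-sum identity |T(N̊)| = |Σ| + r − 1 for pristine binary nets
        for N in tree_child_sample(50, seed=37):
            p = len(internal_tree_nodes(N))
            assert p == len(N.leaves()) + len(N.reticulations()) - 1
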