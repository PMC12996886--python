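"""Network statistics: worked examples, identities, brute-force cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainacn.netpleio import (
    GeneNetwork,
    GeneSet,
    connectivity_score,
    extract_subnetwork,
    jaccard_enrichment,
    mean_connectivity,
    pleiotropy_fraction,
    rank_hub_tfs,
)

from _oracles import (
    connectivity_score_oracle,
    erdos_renyi_edges,
    extract_subnetwork_oracle,
)


def gs(*members, name="set"):
    return GeneSet(name=name, members=frozenset(members))


class TestGeneNetwork:
    def test_undirected_edges_canonicalised_and_deduplicated(self):
        net, dupes = GeneNetwork.from_edges([("b", "a"), ("a", "b"), ("a", "c")],
                                            return_duplicate_count=True)
        assert net.edges == (("a", "b"), ("a", "c"))
        assert dupes == 1

    def test_directed_edges_keep_orientation(self):
        net = GeneNetwork.from_edges([("b", "a")], directed=True)
        assert net.edges == (("b", "a"),)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            GeneNetwork(nodes=frozenset({"a"}), edges=(("a", "a"),))

    def test_degree_counts_both_directions(self):
        net = GeneNetwork.from_edges([("t", "a"), ("b", "t")], directed=True)
        assert net.degree("t") == 2


class TestExtractSubnetwork:
    def test_keeps_only_seed_touching_edges(self):
        net = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("e", "f")])
        sub = extract_subnetwork(net, gs("a"))
        assert sub.edges == (("a", "b"),)  # b-c dropped: no seed endpoint

    def test_all_nodes_as_seeds_gives_largest_component(self):
        net = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("e", "f")])
        sub = extract_subnetwork(net, gs("a", "b", "c", "e", "f"))
        assert sub.nodes == {"a", "b", "c"}

    def test_disjoint_seeds_give_empty_network_with_warning(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.warns(UserWarning, match="no seed"):
            sub = extract_subnetwork(net, gs("zzz"))
        assert sub.nodes == frozenset() and sub.edges == ()

    def test_component_size_tie_broken_lexicographically(self):
        net = GeneNetwork.from_edges([("x", "y"), ("a", "b")])
        sub = extract_subnetwork(net, gs("x", "a"))
        assert sub.nodes == {"a", "b"}

    def test_empty_seed_set_rejected(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="empty"):
            extract_subnetwork(net, gs())

    def test_matches_oracle_on_seeded_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            edges = erdos_renyi_edges(30, 0.2, rng)
            net = GeneNetwork.from_edges(edges)
            names = sorted(net.nodes)
            seeds = set(rng.choice(names, size=5, replace=False))
            want_nodes, want_edges = extract_subnetwork_oracle(edges, seeds)
            got = extract_subnetwork(net, gs(*seeds))
            assert set(got.nodes) == want_nodes
            assert set(got.edges) == want_edges
            # every edge touches a seed and the result is one component
            assert all(u in seeds or v in seeds for u, v in got.edges)


class TestConnectivityScore:
    def test_worked_example_ci4_co8_ni10_no100(self):
        # node X: 8 neighbours, 4 inside a 10-gene subset of a 100-node network
        inside = [f"in{i}" for i in range(4)]
        outside = [f"out{i}" for i in range(4)]
        edges = [("X", n) for n in inside + outside]
        filler = [f"f{i:02d}" for i in range(91)]
        net = GeneNetwork.from_edges(edges, extra_nodes=filler)
        assert len(net.nodes) == 100
        subset = gs(*(inside + [f"f{i:02d}" for i in range(6)]))
        assert connectivity_score(net, subset, "X") == pytest.approx(5.0)

    def test_subset_equal_to_network_scores_one(self):
        net = GeneNetwork.from_edges([("a", "b"), ("b", "c")])
        assert connectivity_score(net, gs(*net.nodes), "b") == pytest.approx(1.0)

    def test_isolated_node_scores_zero(self):
        net = GeneNetwork.from_edges([("a", "b")], extra_nodes=["z"])
        assert connectivity_score(net, gs("a"), "z") == 0.0

    def test_empty_subset_rejected(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="empty"):
            connectivity_score(net, gs(), "a")

    def test_unknown_node_rejected(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="node"):
            connectivity_score(net, gs("a"), "zzz")

    def test_matches_oracle_on_seeded_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            edges = erdos_renyi_edges(30, 0.2, rng)
            net = GeneNetwork.from_edges(edges)
            names = sorted(net.nodes)
            subset = set(rng.choice(names, size=8, replace=False))
            for node in names[:10]:
                got = connectivity_score(net, gs(*subset), node)
                want = connectivity_score_oracle(set(names), edges, subset, node)
                assert got == pytest.approx(want)


class TestMeanConnectivity:
    def test_single_query_equals_node_score(self):
        net = GeneNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        subset = gs("b")
        q_mean, _ = mean_connectivity(net, gs("a"), subset)
        assert q_mean == pytest.approx(connectivity_score(net, subset, "a"))

    def test_complete_graph_scores_match_brute_force(self):
        nodes = list("abcde")
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        net = GeneNetwork.from_edges(edges)
        subset = gs("a", "b")
        # on K5 every node has degree 4; members see 1 in-subset neighbour
        # (self excluded), non-members see 2
        assert connectivity_score(net, subset, "a") == pytest.approx((1 / 4) / (2 / 5))
        assert connectivity_score(net, subset, "c") == pytest.approx((2 / 4) / (2 / 5))

    def test_planted_partition_gives_cs_above_one_inside_block(self):
        rng = np.random.default_rng(0)
        block_a = [f"a{i}" for i in range(10)]
        block_b = [f"b{i}" for i in range(10)]
        edges = []
        for blk in (block_a, block_b):
            for i, u in enumerate(blk):
                for v in blk[i + 1:]:
                    if rng.random() < 0.8:
                        edges.append((u, v))
        for u in block_a:
            for v in block_b:
                if rng.random() < 0.05:
                    edges.append((u, v))
        net = GeneNetwork.from_edges(edges)
        q_mean, bg_mean = mean_connectivity(net, GeneSet("A", frozenset(block_a)),
                                            GeneSet("A", frozenset(block_a)))
        assert q_mean > 1.0
        assert q_mean > bg_mean

    def test_query_absent_from_network_rejected(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="no member"):
            mean_connectivity(net, gs("zzz"), gs("a"))


class TestJaccard:
    def test_worked_example(self):
        assert jaccard_enrichment(gs("a", "b", "c"), gs("b", "c", "d")) == 0.5

    def test_identity_and_disjoint(self):
        assert jaccard_enrichment(gs("a", "b"), gs("a", "b")) == 1.0
        assert jaccard_enrichment(gs("a"), gs("b")) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_enrichment(gs(), gs())

    @given(
        a=st.sets(st.sampled_from("abcdefgh"), max_size=8),
        b=st.sets(st.sampled_from("abcdefgh"), max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        if not a and not b:
            return
        j = jaccard_enrichment(gs(*a), gs(*b))
        assert 0.0 <= j <= 1.0
        assert j == jaccard_enrichment(gs(*b), gs(*a))


class TestRankHubTfs:
    def trn(self):
        edges = [("A", f"t{i}") for i in range(5)] + [("B", f"t{i}") for i in range(3)]
        return GeneNetwork.from_edges(edges, directed=True)

    def test_orders_by_out_degree(self):
        assert rank_hub_tfs(self.trn(), gs("A", "B"), 2) == [("A", 5), ("B", 3)]

    def test_equal_degrees_tie_broken_lexicographically(self):
        edges = [("Z", "t1"), ("Z", "t2"), ("A", "t1"), ("A", "t2")]
        net = GeneNetwork.from_edges(edges, directed=True)
        assert rank_hub_tfs(net, gs("A", "Z"), 5) == [("A", 2), ("Z", 2)]

    def test_k_larger_than_tf_count_returns_all(self):
        assert len(rank_hub_tfs(self.trn(), gs("A", "B"), 10)) == 2

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError, match="k"):
            rank_hub_tfs(self.trn(), gs("A"), 0)

    def test_undirected_network_rejected(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="directed"):
            rank_hub_tfs(net, gs("a"), 1)


class TestPleiotropyFraction:
    def worked(self):
        net = GeneNetwork.from_edges([("T", "g1"), ("T", "g2"), ("T", "g3")], directed=True)
        d1 = GeneSet("D1", frozenset({"g1", "g2"}))
        d2 = GeneSet("D2", frozenset({"g2", "g3"}))
        return net, gs("T"), [d1, d2]

    def test_worked_example_one_third(self):
        net, seeds, disorders = self.worked()
        frac, membership = pleiotropy_fraction(net, seeds, disorders)
        assert frac == pytest.approx(1 / 3)
        assert membership["g2"] == ["D1", "D2"]

    def test_identical_disorder_sets_make_every_gene_pleiotropic(self):
        net, seeds, _ = self.worked()
        d = GeneSet("D", frozenset({"g1", "g2", "g3"}))
        frac, _ = pleiotropy_fraction(net, seeds, [d, GeneSet("D2", d.members)])
        assert frac == 1.0

    def test_disjoint_disorder_sets_give_zero(self):
        net, seeds, _ = self.worked()
        frac, _ = pleiotropy_fraction(net, seeds, [
            GeneSet("D1", frozenset({"g1"})), GeneSet("D2", frozenset({"g2"}))])
        assert frac == 0.0

    def test_growing_a_disorder_set_never_decreases_fraction(self):
        net, seeds, disorders = self.worked()
        base, _ = pleiotropy_fraction(net, seeds, disorders)
        grown = [disorders[0], GeneSet("D2", disorders[1].members | {"g1"})]
        bigger, _ = pleiotropy_fraction(net, seeds, grown)
        assert bigger >= base

    def test_no_interaction_warns_and_returns_nan(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.warns(UserWarning, match="interacts"):
            frac, membership = pleiotropy_fraction(
                net, gs("zzz"), [GeneSet("D1", frozenset({"q"})), GeneSet("D2", frozenset({"r"}))])
        assert np.isnan(frac) and membership == {}

    def test_fewer_than_two_disorder_sets_rejected(self):
        net, seeds, disorders = self.worked()
        with pytest.raises(ValueError, match=">= 2"):
            pleiotropy_fraction(net, seeds, disorders[:1])
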