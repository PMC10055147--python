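import networkx as nx
import numpy as np
import pytest

from bigsur import communities as comm
from bigsur.exceptions import ValidationError

from _oracles import max_modularity_partition, partition_as_sets


def ring_of_triangles(n_cliques=4):
    g = nx.Graph()
    for k in range(n_cliques):
        base = 3 * k
        g.add_edges_from([(base, base + 1), (base, base + 2), (base + 1, base + 2)])
    for k in range(n_cliques):
        g.add_edge(3 * k + 2, (3 * k + 3) % (3 * n_cliques))
    return g


def bridged_cliques(size=5):
    g = nx.disjoint_union(nx.complete_graph(size), nx.complete_graph(size))
    g.add_edge(0, size)
    return g


def anti_correlated_fixture():
    """Two positive 5-cliques joined only by negative cross edges."""
    edges = []
    for grp in ("a", "b"):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((f"{grp}{i}", f"{grp}{j}", 0.5))
    for i in range(5):
        for j in range(5):
            edges.append((f"a{i}", f"b{j}", -0.4))
    return comm.build_graph(edges)


class TestBuildGraph:
    def test_empty(self):
        g = comm.build_graph([])
        assert g.graph.number_of_nodes() == 0
        assert comm.walktrap_communities(g.unweighted_view()).n_communities == 0

    def test_counts(self):
        g = comm.build_graph([("a", "b", 1.0), ("a", "c", 0.5), ("b", "c", 0.2),
                              ("c", "d", 0.1), ("b", "d", 0.3)])
        assert g.graph.number_of_nodes() == 4
        assert g.graph.number_of_edges() == 5

    def test_negative_weight_preserved_and_sign_stripped(self):
        g = comm.build_graph([("a", "b", -0.7), ("b", "c", 0.4)])
        assert g.graph["a"]["b"]["weight"] == -0.7
        view = g.unweighted_view()
        assert view.has_edge("a", "b")  # present despite negative sign
        assert not g.positive_view().has_edge("a", "b")

    def test_conflicting_duplicate_rejected(self):
        with pytest.raises(ValidationError, match="conflicting"):
            comm.build_graph([("a", "b", 0.5), ("a", "b", 0.6)])

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError, match="self-loop"):
            comm.build_graph([("a", "a", 0.5)])


class TestWalktrap:
    def test_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        cs = comm.walktrap_communities(g)
        assert partition_as_sets(cs.assignment) == {
            frozenset(range(5)), frozenset(range(5, 10))
        }

    @pytest.mark.parametrize(
        "graph_factory", [bridged_cliques, ring_of_triangles],
        ids=["bridged-cliques", "ring-of-triangles"],
    )
    def test_matches_exhaustive_modularity_oracle(self, graph_factory):
        g = graph_factory()
        cs = comm.walktrap_communities(g)
        oracle = {frozenset(s) for s in max_modularity_partition(g)}
        assert partition_as_sets(cs.assignment) == oracle

    def test_deterministic(self):
        g = ring_of_triangles()
        a = comm.walktrap_communities(g).assignment
        b = comm.walktrap_communities(g).assignment
        assert a == b

    def test_labels_contiguous_by_size(self):
        g = nx.disjoint_union(nx.complete_graph(7), nx.complete_graph(4))
        cs = comm.walktrap_communities(g)
        assert sorted(set(cs.assignment.values())) == [0, 1]
        assert cs.sizes() == [7, 4]


class TestSplitBySign:
    def test_anti_correlated_community_splits(self):
        g = anti_correlated_fixture()
        initial = comm.walktrap_communities(g.unweighted_view())
        after = comm.split_by_sign(g, initial)
        parts = partition_as_sets(after.assignment)
        assert parts == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_no_negative_edges_unchanged(self):
        g = comm.build_graph([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        cs = comm.walktrap_communities(g.unweighted_view())
        after = comm.split_by_sign(g, cs)
        assert partition_as_sets(after.assignment) == partition_as_sets(cs.assignment)

    def test_all_negative_community_becomes_singletons(self):
        edges = [(f"n{i}", f"n{j}", -0.5) for i in range(4) for j in range(i + 1, 4)]
        g = comm.build_graph(edges)
        cs = comm.walktrap_communities(g.unweighted_view())
        after = comm.split_by_sign(g, cs)
        assert after.n_communities == 4

    def test_never_merges(self):
        g = anti_correlated_fixture()
        initial = comm.walktrap_communities(g.unweighted_view())
        after = comm.split_by_sign(g, initial)
        # every new community is a subset of an old one
        old = partition_as_sets(initial.assignment)
        for new_part in partition_as_sets(after.assignment):
            assert any(new_part <= old_part for old_part in old)


class TestRefineCommunities:
    def test_zero_cross_edges_unchanged(self):
        g = comm.build_graph(
            [("a0", "a1", 0.5), ("a1", "a2", 0.5), ("b0", "b1", 0.5), ("b1", "b2", 0.5)]
        )
        cs = comm.walktrap_communities(g.unweighted_view())
        after = comm.refine_communities(g, cs, merge_ratio_threshold=0.25, max_size=100)
        assert partition_as_sets(after.assignment) == partition_as_sets(cs.assignment)

    def test_dense_cross_edges_merged(self):
        # two triangles with 8 of 9 possible positive cross links
        edges = []
        for grp in ("a", "b"):
            for i in range(3):
                for j in range(i + 1, 3):
                    edges.append((f"{grp}{i}", f"{grp}{j}", 0.9))
        cross = [(i, j) for i in range(3) for j in range(3)][:8]
        edges += [(f"a{i}", f"b{j}", 0.2) for i, j in cross]
        g = comm.build_graph(edges)
        cs = comm.CommunitySet(assignment={**{f"a{i}": 0 for i in range(3)},
                                           **{f"b{i}": 1 for i in range(3)}})
        after = comm.refine_communities(g, cs, merge_ratio_threshold=0.5, max_size=100)
        assert after.n_communities == 1

    def test_oversize_community_resplit(self):
        g = comm.build_graph(
            [(f"a{i}", f"a{j}", 0.5) for i in range(4) for j in range(i + 1, 4)]
            + [(f"b{i}", f"b{j}", 0.5) for i in range(4) for j in range(i + 1, 4)]
            + [("a0", "b0", 0.5)]
        )
        merged = comm.CommunitySet(
            assignment={n: 0 for n in g.graph.nodes}
        )
        after = comm.refine_communities(g, merged, merge_ratio_threshold=0.9, max_size=5)
        assert after.n_communities == 2

    def test_partition_invariant_through_pipeline(self):
        g = anti_correlated_fixture()
        cs = comm.walktrap_communities(g.unweighted_view())
        for stage in (comm.split_by_sign(g, cs),
                      comm.refine_communities(g, comm.split_by_sign(g, cs))):
            assert set(stage.assignment) == set(g.graph.nodes)  # coverage
            assert min(stage.assignment.values()) == 0
            assert max(stage.assignment.values()) == stage.n_communities - 1


class TestTopConnectedFeatures:
    def test_small_community_returns_all(self):
        g = comm.build_graph([("a", "b", 0.5), ("b", "c", 0.5)])
        cs = comm.CommunitySet(assignment={"a": 0, "b": 0, "c": 0})
        feats = comm.top_connected_features(g, cs, [0], k=75)
        assert set(feats[0]) == {"a", "b", "c"}

    def test_star_hub_first(self):
        g = comm.build_graph([("hub", f"x{i}", 0.5) for i in range(5)])
        cs = comm.CommunitySet(assignment={n: 0 for n in g.graph.nodes})
        feats = comm.top_connected_features(g, cs, [0], k=3)
        assert feats[0][0] == "hub"

    def test_known_degree_ordering(self):
        # degrees: a:3, b:2, c:2, d:1; tie b/c broken by weight sum
        g = comm.build_graph([("a", "b", 0.9), ("a", "c", 0.4), ("a", "d", 0.3),
                              ("b", "c", 0.2)])
        cs = comm.CommunitySet(assignment={n: 0 for n in g.graph.nodes})
        feats = comm.top_connected_features(g, cs, [0], k=4)
        assert feats[0] == ["a", "b", "c", "d"]

    def test_unknown_label_rejected(self):
        g = comm.build_graph([("a", "b", 0.5)])
        cs = comm.CommunitySet(assignment={"a": 0, "b": 0})
        with pytest.raises(ValidationError):
            comm.top_connected_features(g, cs, [7])


class TestPairEnrichment:
    def test_fold_ten_hand_computed(self):
        genes = [f"g{i}" for i in range(10)]  # 45 possible pairs
        ref = {frozenset((genes[i], genes[i + 1])) for i in range(0, 9, 2)}  # 5 pairs
        # reference covers 5/45 of possible pairs; all significant pairs inside it
        sig = set(list(ref)[:3])
        report = comm.pair_enrichment(sig, ref, genes)
        assert report.observed_fraction == pytest.approx(1.0)
        assert report.expected_fraction == pytest.approx(5 / 45)
        assert report.fold_enrichment == pytest.approx(9.0)

    def test_disjoint_reference_fold_zero(self):
        genes = [f"g{i}" for i in range(6)]
        sig = {frozenset(("g0", "g1"))}
        ref = {frozenset(("g2", "g3"))}
        assert comm.pair_enrichment(sig, ref, genes).fold_enrichment == 0.0

    def test_random_pairs_fold_near_one(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        all_pairs = [frozenset((a, b)) for i, a in enumerate(genes) for b in genes[i + 1:]]
        ref = {p for p in all_pairs if rng.random() < 0.3}
        sig = {all_pairs[i] for i in rng.choice(len(all_pairs), 300, replace=False)}
        fold = comm.pair_enrichment(sig, ref, genes).fold_enrichment
        assert 0.8 < fold < 1.2

    def test_empty_significant_rejected(self):
        with pytest.raises(ValidationError):
            comm.pair_enrichment(set(), {frozenset(("a", "b"))}, ["a", "b"])
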