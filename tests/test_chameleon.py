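"""Graph construction, balanced bisection, RI/RC, merging and pruning."""

import itertools

import networkx as nx
import numpy as np
import pytest

import biafs
from biafs.chameleon import (ClusterState, FeatureGraph, balanced_min_bisection,
                             pair_similarity, relative_closeness,
                             relative_interconnectivity, target_distances)


def graph_from_edges(vertices, edges) -> FeatureGraph:
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return FeatureGraph(graph=g, names=tuple(vertices), k_neighbors=1)


def brute_force_bisection(vertices, fg):
    """Oracle: enumerate every balanced split directly."""
    verts = sorted(vertices)
    s = len(verts)
    best = None
    for a in itertools.combinations(verts, (s + 1) // 2):
        b = [v for v in verts if v not in a]
        cut = sum(fg.weight(u, v) for u in a for v in b)
        if best is None or cut < best:
            best = cut
    return best


class TestFeatureSimilarity:
    def test_negation_and_duplicate_have_similarity_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        fm = biafs.FeatureMatrix(values=np.column_stack([x, -x, x.copy()]),
                                 feature_names=["a", "b", "c"],
                                 feature_kinds=["primary"] * 3)
        sim = biafs.feature_similarity(fm)
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(sim), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        fm = biafs.FeatureMatrix(values=rng.standard_normal((1000, 5)),
                                 feature_names=list("abcde"),
                                 feature_kinds=["primary"] * 5)
        sim = biafs.feature_similarity(fm)
        off = sim[~np.eye(5, dtype=bool)]
        assert off.max() < 0.1

    def test_constant_feature_zero_similarity(self):
        fm = biafs.FeatureMatrix(values=np.column_stack([np.arange(10.0), np.full(10, 3.0)]),
                                 feature_names=["a", "c"], feature_kinds=["primary"] * 2)
        sim = biafs.feature_similarity(fm)
        assert sim[0, 1] == 0.0


class TestKnnGraph:
    def test_saturation_gives_complete_graph(self):
        rng = np.random.default_rng(2)
        sim = np.abs(np.corrcoef(rng.standard_normal((20, 6)), rowvar=False))
        fg = biafs.build_knn_graph(sim, list("abcdef"), k_neighbors=5)
        assert fg.graph.number_of_edges() == 15

    def test_two_blocks_stay_separate(self):
        # two blocks of mutually similar features, near-zero cross-similarity
        names = ["a1", "a2", "a3", "b1", "b2", "b3"]
        sim = np.full((6, 6), 0.01)
        sim[:3, :3] = 0.9
        sim[3:, 3:] = 0.9
        np.fill_diagonal(sim, 1.0)
        fg = biafs.build_knn_graph(sim, names, k_neighbors=2)
        for u, v in fg.graph.edges:
            assert u[0] == v[0], f"cross-block edge {u}-{v}"

    def test_tie_broken_lexicographically(self):
        # c's single nearest neighbour is tied between a and b -> a wins
        sim = np.array([[1.0, 0.0, 0.5],
                        [0.0, 1.0, 0.5],
                        [0.5, 0.5, 1.0]])
        fg = biafs.build_knn_graph(sim, ["a", "b", "c"], k_neighbors=1)
        assert fg.graph.has_edge("c", "a")
        # b also picks its own nearest (c), so degree >= 1 everywhere
        assert min(dict(fg.graph.degree).values()) >= 1


class TestBalancedMinBisection:
    def test_two_vertex_path(self):
        fg = graph_from_edges(["a", "b"], [("a", "b", 0.7)])
        res = balanced_min_bisection(["a", "b"], fg)
        assert res.cut_weight == pytest.approx(0.7)
        assert res.mean_cut_weight == pytest.approx(0.7)

    def test_unit_four_cycle(self):
        fg = graph_from_edges("abcd", [("a", "b", 1.0), ("b", "c", 1.0),
                                       ("c", "d", 1.0), ("d", "a", 1.0)])
        res = balanced_min_bisection("abcd", fg)
        assert res.cut_weight == pytest.approx(2.0)   # opposite-pair split

    def test_two_triangles_weak_bridge(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0),
                 ("c", "d", 0.1)]
        fg = graph_from_edges("abcdef", edges)
        res = balanced_min_bisection("abcdef", fg)
        assert res.cut_weight == pytest.approx(brute_force_bisection("abcdef", fg))
        assert res.cut_weight == pytest.approx(0.1)
        assert set(res.part_a) in ({"a", "b", "c"}, {"d", "e", "f"})

    @pytest.mark.parametrize("size", [5, 8, 11])
    def test_heuristic_matches_enumeration(self, size):
        rng = np.random.default_rng(size)
        names = [f"v{i}" for i in range(size)]
        edges = [(names[i], names[j], float(rng.uniform(0, 1)))
                 for i in range(size) for j in range(i + 1, size)
                 if rng.uniform() < 0.7]
        fg = graph_from_edges(names, edges)
        exact = balanced_min_bisection(names, fg, method="exhaustive")
        local = balanced_min_bisection(names, fg, method="local",
                                       rng=np.random.default_rng(0))
        assert local.cut_weight == pytest.approx(exact.cut_weight, abs=1e-12)


TOY_EDGES = [("a", "b", 1.0), ("c", "d", 1.0), ("b", "c", 0.5)]


@pytest.fixture()
def toy_state():
    fg = graph_from_edges("abcd", TOY_EDGES)
    return ClusterState(fg=fg, clusters=[("a", "b"), ("c", "d")], seed=0)


class TestRiRc:
    def test_toy_values(self, toy_state):
        ri = relative_interconnectivity(("a", "b"), ("c", "d"), toy_state)
        rc = relative_closeness(("a", "b"), ("c", "d"), toy_state)
        assert ri == pytest.approx(0.5)   # 0.5 / ((1 + 1)/2)
        assert rc == pytest.approx(0.5)   # 0.5 / (0.5*1 + 0.5*1)

    def test_symmetry(self, toy_state):
        assert relative_interconnectivity(("c", "d"), ("a", "b"), toy_state) == \
               relative_interconnectivity(("a", "b"), ("c", "d"), toy_state)

    def test_no_cross_edges_gives_zero(self):
        fg = graph_from_edges("abcd", [("a", "b", 1.0), ("c", "d", 1.0)])
        st = ClusterState(fg=fg, clusters=[("a", "b"), ("c", "d")], seed=0)
        assert relative_interconnectivity(("a", "b"), ("c", "d"), st) == 0.0
        assert relative_closeness(("a", "b"), ("c", "d"), st) == 0.0

    def test_identical_scales_give_rc_one(self):
        edges = [("a", "b", 0.6), ("c", "d", 0.6), ("b", "c", 0.6)]
        st = ClusterState(fg=graph_from_edges("abcd", edges),
                          clusters=[("a", "b"), ("c", "d")], seed=0)
        assert relative_closeness(("a", "b"), ("c", "d"), st) == pytest.approx(1.0)


class TestPairSimilarity:
    @pytest.mark.parametrize("ri,rc,alpha,expected", [
        (0.0, 0.0, 1.0, 0.0),
        (0.4, 0.9, 0.0, 0.4),     # alpha=0 reduces to RI
        (0.5, 0.5, 2.0, 0.125),
    ])
    def test_values(self, ri, rc, alpha, expected):
        assert pair_similarity(ri, rc, alpha) == pytest.approx(expected)

    def test_monotone(self):
        assert pair_similarity(0.6, 0.5) >= pair_similarity(0.4, 0.5)
        assert pair_similarity(0.4, 0.7) >= pair_similarity(0.4, 0.5)


class TestInitialPartition:
    def test_two_cliques_recovered(self):
        edges = [("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9),
                 ("d", "e", 0.9), ("e", "f", 0.9), ("d", "f", 0.9)]
        fg = graph_from_edges("abcdef", edges)
        st = biafs.initial_partition(fg, k_init=2, seed=0)
        assert sorted(st.clusters) == [("a", "b", "c"), ("d", "e", "f")]

    def test_all_singletons(self):
        fg = graph_from_edges("abcd", [("a", "b", 0.5), ("c", "d", 0.5)])
        st = biafs.initial_partition(fg, k_init=4, seed=0)
        assert all(len(c) == 1 for c in st.clusters)

    def test_planted_three_blocks(self):
        # 12 vertices in disconnected blocks of 6, 3 and 3: every recursive
        # balanced split can fall on a zero-cut block boundary
        blocks = [["a1", "a2", "a3"], ["b1", "b2", "b3"],
                  ["z1", "z2", "z3", "z4", "z5", "z6"]]
        edges = []
        for block in blocks:
            edges += [(u, v, 0.9) for u, v in itertools.combinations(block, 2)]
        fg = graph_from_edges([v for b in blocks for v in b], edges)
        st = biafs.initial_partition(fg, k_init=3, seed=0)
        assert sorted(st.clusters) == sorted(tuple(b) for b in blocks)


class TestMerge:
    def test_noop_when_target_reached(self, toy_state):
        st = biafs.mchameleon_merge(toy_state, k_target=2)
        assert st.clusters == toy_state.clusters
        assert st.merge_trace == []

    def test_duplicated_pairs_cluster_together(self):
        # features duplicated in two pairs; the pairs must become the clusters
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        fm = biafs.FeatureMatrix(
            values=np.column_stack([x, x + 1e-3 * rng.standard_normal(50),
                                    y, y + 1e-3 * rng.standard_normal(50)]),
            feature_names=["x1", "x2", "y1", "y2"], feature_kinds=["primary"] * 4)
        sim = biafs.feature_similarity(fm)
        fg = biafs.build_knn_graph(sim, fm.feature_names, k_neighbors=2)
        st = biafs.initial_partition(fg, k_init=4, seed=0)
        st = biafs.mchameleon_merge(st, k_target=2)
        assert sorted(st.clusters) == [("x1", "x2"), ("y1", "y2")]

    def test_trace_length_counts_merges(self, cohort):
        table, _ = cohort
        fmz = biafs.zscore_normalize(biafs.expand_features(table))
        sub = fmz.subset(["W", "A", "G", "R4", "R5", "1/R4", "R4R5", "R4^2"])
        sim = biafs.feature_similarity(sub)
        fg = biafs.build_knn_graph(sim, sub.feature_names, k_neighbors=3)
        st = biafs.initial_partition(fg, k_init=8, seed=0)
        merged = biafs.mchameleon_merge(st, k_target=3)
        assert len(merged.merge_trace) == 8 - 3
        assert merged.h == 3

    def test_cache_consistency_after_merges(self, cohort):
        table, _ = cohort
        fmz = biafs.zscore_normalize(biafs.expand_features(table))
        sub = fmz.subset(["W", "A", "G", "H", "R4", "R5", "1/R4", "1/R5", "R4R5"])
        sim = biafs.feature_similarity(sub)
        fg = biafs.build_knn_graph(sim, sub.feature_names, k_neighbors=3)
        st = biafs.mchameleon_merge(biafs.initial_partition(fg, k_init=9, seed=1),
                                    k_target=3)
        for cluster in st.clusters:
            cached = st.internal[cluster]
            fresh = st.recompute_internal(cluster)
            assert cached == pytest.approx(fresh, abs=1e-10)

    def test_merge_requires_enough_clusters(self, toy_state):
        with pytest.raises(ValueError):
            biafs.mchameleon_merge(toy_state, k_target=5)


class TestReduction:
    @staticmethod
    def _state_with_sizes(fm, sizes):
        names = list(fm.feature_names)
        clusters, i = [], 0
        for s in sizes:
            clusters.append(tuple(sorted(names[i:i + s])))
            i += s
        sim = biafs.feature_similarity(fm)
        fg = biafs.build_knn_graph(sim, names, k_neighbors=3)
        return ClusterState(fg=fg, clusters=clusters, seed=0)

    @pytest.fixture()
    def fm14(self, cohort):
        table, _ = cohort
        fmz = biafs.zscore_normalize(biafs.expand_features(table))
        keep = fmz.feature_names[:14]
        return fmz.subset(keep), table.target("BFM")

    def test_prune_counts_match_cluster_sizes(self, fm14):
        fm, y = fm14
        st = self._state_with_sizes(fm, [2, 5, 5, 2])
        survivors, removed = biafs.prune_far_from_target(st, fm, y, m_remove=1)
        assert len(survivors) == 10        # one removed per cluster: 14 -> 10
        assert len(removed) == 4

    def test_prune_zero_is_identity(self, fm14):
        fm, y = fm14
        st = self._state_with_sizes(fm, [7, 7])
        survivors, removed = biafs.prune_far_from_target(st, fm, y, m_remove=0)
        assert survivors == list(fm.feature_names)
        assert removed == {}

    def test_prune_never_empties_singleton(self, fm14):
        fm, y = fm14
        st = self._state_with_sizes(fm, [1, 13])
        survivors, removed = biafs.prune_far_from_target(st, fm, y, m_remove=1)
        singleton = st.clusters[0] if len(st.clusters[0]) == 1 else st.clusters[1]
        assert singleton[0] in survivors

    def test_prune_removes_farthest(self, fm14):
        fm, y = fm14
        st = self._state_with_sizes(fm, [14])
        dist = target_distances(st, fm, y)
        _, removed = biafs.prune_far_from_target(st, fm, y, m_remove=1)
        (name, (_, d)), = removed.items()
        assert d == pytest.approx(max(dist.values()))

    def test_representatives_one_per_cluster(self, fm14, cohort):
        table, _ = cohort
        fm, y = fm14
        st = self._state_with_sizes(fm, [4, 4, 3, 3])
        filt = biafs.rank_and_filter(fm, y, top_k=14, seed=0)
        reps = biafs.select_representatives(st, filt.score_map())
        assert len(reps) == 4
        by_cluster = {c: max((filt.score_map()[n].score for n in c)) for c in st.clusters}
        assert {filt.score_map()[r].score for r in reps} == set(by_cluster.values())

    def test_representatives_tie_broken_by_rank(self):
        scores = [biafs.HSICScore("a", 1.0, None, 2), biafs.HSICScore("b", 1.0, None, 1)]
        fg = graph_from_edges(["a", "b"], [("a", "b", 0.5)])
        st = ClusterState(fg=fg, clusters=[("a", "b")], seed=0)
        assert biafs.select_representatives(st, scores) == ["b"]
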