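import math
import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from minenet import (
    Cluster,
    ClusteringParams,
    cluster_from_members,
    compute_vertex_weights,
    grow_cluster,
    local_modularity,
    maybe_merge,
    ring_of_cliques,
    run_mine,
    score_cluster,
    trim_cluster,
)

from _reference import reference_mine
from conftest import random_graph


def two_triangles_bridged():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                  ("x", "y"), ("y", "z"), ("x", "z"), ("a", "x")])
    return g


class TestLocalModularity:
    def test_triangle_with_bridge(self):
        g = two_triangles_bridged()
        assert local_modularity(g, {"a", "b", "c"}) == pytest.approx(3.0)

    def test_whole_component_is_infinite(self, triangle):
        assert local_modularity(triangle, {"a", "b", "c"}) == math.inf

    def test_singleton_is_zero(self, path3):
        assert local_modularity(path3, {"b"}) == 0.0

    def test_unknown_member_raises(self, triangle):
        with pytest.raises(KeyError):
            local_modularity(triangle, {"a", "q"})


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [{"vwp": -0.1}, {"vwp": 1.5}, {"msp": 2.0}, {"mp": 0.0}, {"min_size": 0}],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClusteringParams(**kwargs)

    def test_defaults_are_published_operating_point(self):
        p = ClusteringParams()
        assert (p.vwp, p.msp, p.mp, p.trim, p.min_size) == (0.9, 0.3, 0.5, True, 3)


class TestGrowCluster:
    def test_bridged_k4s_recovers_one_clique(self, bridged_k4s):
        w = compute_vertex_weights(bridged_k4s)
        params = ClusteringParams(vwp=1.0, msp=0.0, trim=False)
        c = grow_cluster(bridged_k4s, w, "a2", params)
        assert c.members == frozenset({"a1", "a2", "a3", "a4"})
        assert (c.e_in, c.e_out) == (6, 1)

    def test_isolated_triangle_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("p", "q")])
        w = compute_vertex_weights(g)
        c = grow_cluster(g, w, "a", ClusteringParams(vwp=1.0, msp=0.0, trim=False))
        assert c.members == frozenset({"a", "b", "c"})
        assert c.local_modularity == math.inf

    def test_k4_all_admitted_with_strict_weight_test(self, k4):
        w = compute_vertex_weights(k4)
        c = grow_cluster(k4, w, "a", ClusteringParams(vwp=0.0, msp=0.0, trim=False))
        assert c.members == frozenset({"a", "b", "c", "d"})

    def test_unknown_seed_raises(self, k4):
        w = compute_vertex_weights(k4)
        with pytest.raises(KeyError):
            grow_cluster(k4, w, "zz", ClusteringParams())


class TestTrim:
    def test_pendant_removed(self, triangle):
        g = triangle.copy()
        g.add_edge("a", "d")
        c = cluster_from_members(g, {"a", "b", "c", "d"})
        assert trim_cluster(g, c).members == frozenset({"a", "b", "c"})

    def test_path_loses_both_ends_in_one_pass(self, path3):
        c = cluster_from_members(path3, {"a", "b", "c"})
        # simultaneous pass: both endpoints have in-cluster degree 1
        assert trim_cluster(path3, c).members == frozenset({"b"})

    def test_k4_unchanged(self, k4):
        c = cluster_from_members(k4, set(k4.nodes()))
        assert trim_cluster(k4, c).members == c.members


class TestMerge:
    def _cluster(self, graph, members):
        return cluster_from_members(graph, members)

    def test_identical_candidate_merges(self, bridged_k4s):
        existing = [self._cluster(bridged_k4s, {"a1", "a2", "a3", "a4"})]
        out = maybe_merge(
            existing, self._cluster(bridged_k4s, {"a1", "a2", "a3", "a4"}),
            mp=0.5, graph=bridged_k4s,
        )
        assert len(out) == 1

    def test_disjoint_candidate_appended(self, bridged_k4s):
        existing = [self._cluster(bridged_k4s, {"a1", "a2", "a3"})]
        out = maybe_merge(
            existing, self._cluster(bridged_k4s, {"b1", "b2", "b3"}),
            mp=0.5, graph=bridged_k4s,
        )
        assert len(out) == 2

    def test_half_overlap_of_smaller_merges_and_recomputes(self):
        g = nx.path_graph([f"v{i}" for i in range(1, 7)])
        existing = [cluster_from_members(g, {"v1", "v2", "v3", "v4"})]
        cand = cluster_from_members(g, {"v3", "v4", "v5", "v6"})
        out = maybe_merge(existing, cand, mp=0.5, graph=g)
        assert len(out) == 1
        assert out[0].members == frozenset({"v1", "v2", "v3", "v4", "v5", "v6"})
        assert out[0].e_in == 5 and out[0].e_out == 0  # stats recomputed on union

    def test_first_existing_cluster_wins(self, bridged_k4s):
        first = self._cluster(bridged_k4s, {"a1", "a2", "b1"})
        second = self._cluster(bridged_k4s, {"a1", "a2", "a3"})
        out = maybe_merge(
            [first, second], self._cluster(bridged_k4s, {"a1", "a2", "a4"}),
            mp=0.5, graph=bridged_k4s,
        )
        assert out[0].members == frozenset({"a1", "a2", "a4", "b1"})
        assert out[1].members == second.members


class TestScore:
    def test_k4_scores_four(self, k4):
        assert score_cluster(k4, cluster_from_members(k4, set(k4.nodes()))) == 4.0

    def test_path_of_three_scores_two(self, path3):
        c = cluster_from_members(path3, {"a", "b", "c"})
        assert score_cluster(path3, c) == pytest.approx(2.0)

    def test_singleton_scores_zero(self, path3):
        assert score_cluster(path3, cluster_from_members(path3, {"a"})) == 0.0


class TestRunMine:
    def test_ring_of_cliques_recovered_exactly(self):
        g, _ = ring_of_cliques(5, 6, 0, seed=0)
        clusters = run_mine(g, ClusteringParams(vwp=1.0, msp=0.0, trim=False))
        assert len(clusters) == 5
        for c in clusters:
            assert len(c.members) == 6
            assert c.density == pytest.approx(1.0)
            assert (c.e_in, c.e_out) == (15, 2)
            assert c.local_modularity == pytest.approx(7.5)

    def test_edgeless_graph_yields_nothing(self):
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(7))
        assert run_mine(g, ClusteringParams()) == []

    def test_empty_graph(self):
        assert run_mine(nx.Graph(), ClusteringParams()) == []

    def test_k3_with_isolated_nodes(self, triangle):
        g = triangle.copy()
        g.add_nodes_from(f"iso{i}" for i in range(10))
        clusters = run_mine(g, ClusteringParams())
        assert len(clusters) == 1
        assert clusters[0].members == frozenset({"a", "b", "c"})

    def test_min_size_filter(self):
        g, _ = ring_of_cliques(3, 4, 0, seed=0)
        clusters = run_mine(g, ClusteringParams(vwp=1.0, msp=0.0, min_size=5))
        assert clusters == []

    def test_determinism_is_independent_of_insertion_order(self):
        g1, _ = ring_of_cliques(4, 5, 3, seed=9)
        g2 = nx.Graph()
        g2.add_nodes_from(sorted(g1.nodes(), reverse=True))
        g2.add_edges_from(sorted(g1.edges(), reverse=True))
        params = ClusteringParams()
        r1, r2 = run_mine(g1, params), run_mine(g2, params)
        assert [c.members for c in r1] == [c.members for c in r2]
        assert [(c.e_in, c.e_out, c.score) for c in r1] == [
            (c.e_in, c.e_out, c.score) for c in r2
        ]

    @pytest.mark.parametrize("mp", [0.5, 1.0])
    def test_clusters_are_non_exclusive(self, mp):
        # two K5s sharing one articulation node: both cliques are recovered
        # and the shared node belongs to both output clusters
        g = nx.Graph()
        groups = (["a1", "a2", "a3", "a4", "s"], ["s", "b1", "b2", "b3", "b4"])
        for group in groups:
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(group[i], group[j])
        clusters = run_mine(g, ClusteringParams(vwp=1.0, msp=0.0, mp=mp, trim=False))
        assert {c.members for c in clusters} == {
            frozenset(groups[0]), frozenset(groups[1]),
        }
        assert clusters[0].members & clusters[1].members == {"s"}

    @pytest.mark.parametrize("seed", range(6))
    def test_merge_threshold_monotone_on_random_graphs(self, seed):
        g = random_graph(random.Random(seed), 10, 0.35)
        counts = [
            len(run_mine(g, ClusteringParams(vwp=0.9, msp=0.3, mp=mp)))
            for mp in (0.3, 0.5, 0.8, 1.0)
        ]
        assert counts == sorted(counts)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 10),
           p=st.floats(0.1, 0.8))
    def test_outputs_respect_min_size_and_membership(self, seed, n, p):
        g = random_graph(random.Random(seed), n, p)
        params = ClusteringParams()
        for c in run_mine(g, params):
            assert len(c.members) >= params.min_size
            assert c.members <= set(g.nodes())
            assert c.score == pytest.approx(c.density * len(c.members))


class TestReferenceInterpreterAgreement:
    @pytest.mark.parametrize("vwp,msp,trim", [
        (1.0, 0.0, False), (0.9, 0.3, True), (0.5, 0.5, True), (0.0, 0.0, False),
    ])
    def test_small_random_graphs_match(self, vwp, msp, trim):
        rng = random.Random(hash((vwp, msp, trim)) % (2**31))
        for _ in range(25):
            g = random_graph(rng, rng.randint(2, 8), rng.uniform(0.15, 0.8))
            params = ClusteringParams(vwp=vwp, msp=msp, trim=trim)
            ours = [c.members for c in run_mine(g, params)]
            ref = reference_mine(g, vwp, msp, params.mp, trim, params.min_size)
            assert ours == ref
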