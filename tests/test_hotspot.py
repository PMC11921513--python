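"""Attribute annotation, gradient-weighted single linkage, gap cut and
community classification."""

import numpy as np
import pytest

from tdahotspot import (
    ClustererSpec,
    DataMatrix,
    HotspotConfig,
    MapperGraph,
    MapperVertex,
    RejectionReason,
    build_mapper,
    classify_communities,
    cut_dendrogram,
    detect_hotspots,
    mad,
    single_linkage_on_graph,
)
from tdahotspot.hotspot import annotate_attribute, annotate_gradient

from conftest import toy_graph


class TestAnnotate:
    def test_vertex_mean_is_arithmetic_mean(self):
        graph = toy_graph([{0, 1, 2, 3}], attr=[0, 1, 1, 0])
        assert graph.vertices[0].attr_mean == pytest.approx(0.5)

    def test_constant_attribute(self):
        graph = toy_graph([{0, 1}], attr=[1, 1])
        assert graph.vertices[0].attr_mean == 1.0

    def test_singleton_vertex(self):
        graph = toy_graph([{2}], attr=[0.0, 0.0, 0.7])
        assert graph.vertices[0].attr_mean == pytest.approx(0.7)

    def test_out_of_range_member_raises(self):
        graph = toy_graph([{5}])
        with pytest.raises(IndexError):
            annotate_attribute(graph, np.array([1.0, 2.0]))

    def test_gradient_is_absolute_difference(self):
        graph = toy_graph([{0, 1}, {1, 2}], attr=[0.2, 0.2, 1.6])
        # vertex means 0.2 and 0.9
        assert graph.edges[(0, 1)] == pytest.approx(0.7)

    def test_gradient_zero_for_equal_means(self):
        graph = toy_graph([{0, 1}, {1, 2}], attr=[0.4, 0.4, 0.4])
        assert graph.edges[(0, 1)] == 0.0

    def test_triangle_gradients(self):
        # triangle v0={0,3}, v1={3,4}, v2={4,0} with means (0, 0.5, 1)
        graph = toy_graph(
            [{0, 3}, {3, 4}, {4, 0}], attr=[0.5, 0.0, 0.0, -0.5, 1.5]
        )
        got = sorted(graph.edges.values())
        assert got == pytest.approx([0.5, 0.5, 1.0])


def naive_single_linkage_heights(n_vertices, edge_weights):
    """O(V^3) single linkage on the full distance matrix with +inf for
    non-edges; returns the sorted list of finite merge heights."""
    INF = float("inf")
    dist = {
        (i, j): INF for i in range(n_vertices) for j in range(n_vertices) if i < j
    }
    for (u, v), w in edge_weights.items():
        dist[(min(u, v), max(u, v))] = w
    clusters = [{i} for i in range(n_vertices)]
    heights = []
    while len(clusters) > 1:
        best = (INF, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(
                    dist[(min(i, j), max(i, j))]
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if d < best[0]:
                    best = (d, a, b)
        if best[1] is None:  # only infinitely distant clusters remain
            break
        d, a, b = best
        heights.append(d)
        clusters[a] |= clusters[b]
        del clusters[b]
    return sorted(heights)


class TestSingleLinkage:
    def test_path_merge_heights(self):
        graph = MapperGraph(
            vertices=[MapperVertex(id=i, members=frozenset({i}), interval_index=0)
                      for i in range(3)],
            edges={(0, 1): 0.1, (1, 2): 0.9},
        )
        dendrogram = single_linkage_on_graph(graph)
        assert list(dendrogram.heights()) == pytest.approx([0.1, 0.9])

    def test_isolated_vertices_never_merge(self):
        graph = MapperGraph(
            vertices=[MapperVertex(id=i, members=frozenset({i}), interval_index=0)
                      for i in range(2)],
            edges={},
        )
        assert single_linkage_on_graph(graph).merges == ()

    def test_tree_heights_are_sorted_edge_weights(self):
        rng = np.random.default_rng(0)
        weights = rng.uniform(size=4)
        edges = {(0, 1): weights[0], (1, 2): weights[1], (1, 3): weights[2],
                 (3, 4): weights[3]}
        graph = MapperGraph(
            vertices=[MapperVertex(id=i, members=frozenset({i}), interval_index=0)
                      for i in range(5)],
            edges=edges,
        )
        got = sorted(single_linkage_on_graph(graph).heights())
        assert got == pytest.approx(sorted(weights))

    @pytest.mark.parametrize("trial", range(200))
    def test_matches_naive_oracle_on_random_graphs(self, trial):
        """Graph-restricted Kruskal single linkage reproduces naive
        single-linkage merge heights on random (not necessarily connected)
        graphs with up to 6 vertices."""
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(2, 7))
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    edges[(i, j)] = float(np.round(rng.uniform(), 3))
        graph = MapperGraph(
            vertices=[MapperVertex(id=i, members=frozenset({i}), interval_index=0)
                      for i in range(n)],
            edges=edges,
        )
        got = sorted(single_linkage_on_graph(graph).heights())
        expected = naive_single_linkage_heights(n, edges)
        assert got == pytest.approx(expected)


class TestCutDendrogram:
    def test_path_with_single_gap_splits_in_two(self):
        # path of four vertices with means (0, 0, 1, 1): F' = (0, 1, 0)
        graph = MapperGraph(
            vertices=[MapperVertex(id=i, members=frozenset({i}), interval_index=0)
                      for i in range(4)],
            edges={(0, 1): None, (1, 2): None, (2, 3): None},
        )
        annotate_attribute(graph, np.array([0.0, 0.0, 1.0, 1.0]))
        annotate_gradient(graph)
        dendrogram = single_linkage_on_graph(graph)
        communities = cut_dendrogram(dendrogram, graph)
        got = {frozenset(c.vertex_ids) for c in communities}
        assert got == {frozenset({0, 1}), frozenset({2, 3})}

    def test_all_zero_gradients_one_community_per_component(self):
        graph = toy_graph([{0, 1}, {1, 2}, {5, 6}, {6, 7}], attr=[1.0] * 8)
        communities = cut_dendrogram(single_linkage_on_graph(graph), graph)
        assert {frozenset(c.vertex_ids) for c in communities} == {
            frozenset({0, 1}),
            frozenset({2, 3}),
        }

    def test_single_vertex_graph(self):
        graph = toy_graph([{0}], attr=[1.0])
        communities = cut_dendrogram(single_linkage_on_graph(graph), graph)
        assert len(communities) == 1 and communities[0].vertex_ids == {0}

    def test_matches_exhaustive_threshold_sweep(self):
        """On random annotated graphs the largest-gap cut equals the best
        threshold from an exhaustive sweep over candidate taus."""
        rng = np.random.default_rng(77)
        for _ in range(40):
            n_samples = 30
            attr = rng.random(n_samples)
            sets = [
                set(rng.choice(n_samples, size=3, replace=False).tolist())
                for _ in range(rng.integers(2, 9))
            ]
            graph = toy_graph(sets, attr=attr)
            dendrogram = single_linkage_on_graph(graph)
            communities = cut_dendrogram(dendrogram, graph)
            # partition invariant
            all_vids = sorted(v for c in communities for v in c.vertex_ids)
            assert all_vids == sorted(v.id for v in graph.vertices)
            heights = np.unique(dendrogram.heights())
            if len(heights) > 1 and np.max(np.diff(heights)) > 0:
                gaps = np.diff(heights)
                best = int(np.argmax(gaps))
                tau = (heights[best] + heights[best + 1]) / 2
                kept = MapperGraph(
                    vertices=graph.vertices,
                    edges={e: w for e, w in graph.edges.items() if w < tau},
                )
                expected = {frozenset(c) for c in kept.connected_components()}
                assert {frozenset(c.vertex_ids) for c in communities} == expected

    def test_per_component_cut_uses_local_gaps(self):
        """Two components whose merge-height scales differ: the pooled cut
        leaves the small-scale component whole, the per-component cut splits
        it at its own largest gap."""
        graph = MapperGraph(
            vertices=[MapperVertex(id=i, members=frozenset({i}), interval_index=0)
                      for i in range(6)],
            edges={(0, 1): 0.0, (1, 2): 1.0, (3, 4): 0.4, (4, 5): 0.5},
        )
        annotate_attribute(graph, np.linspace(0.0, 1.0, 6))
        dendrogram = single_linkage_on_graph(graph)
        pooled = cut_dendrogram(dendrogram, graph)
        # pooled distinct heights {0, 0.4, 0.5, 1}: tau in (0.5, 1)
        assert {frozenset(c.vertex_ids) for c in pooled} == {
            frozenset({0, 1}), frozenset({2}), frozenset({3, 4, 5}),
        }
        local = cut_dendrogram(dendrogram, graph, per_component=True)
        # component {3,4,5} has heights {0.4, 0.5}: its own tau is 0.45
        assert {frozenset(c.vertex_ids) for c in local} == {
            frozenset({0, 1}), frozenset({2}), frozenset({3, 4}), frozenset({5}),
        }

    def test_intra_community_homogeneity(self):
        """Within-community edges all lie below the cut; cross-community
        edges within one dendrogram component lie at or above it."""
        rng = np.random.default_rng(13)
        attr = rng.random(40)
        sets = [set(rng.choice(40, size=4, replace=False).tolist()) for _ in range(10)]
        graph = toy_graph(sets, attr=attr)
        dendrogram = single_linkage_on_graph(graph)
        communities = cut_dendrogram(dendrogram, graph)
        heights = np.unique(dendrogram.heights())
        if len(heights) <= 1:
            return
        gaps = np.diff(heights)
        tau = (heights[np.argmax(gaps)] + heights[np.argmax(gaps) + 1]) / 2
        comm_of = {}
        for ci, c in enumerate(communities):
            for vid in c.vertex_ids:
                comm_of[vid] = ci
        for (u, v), w in graph.edges.items():
            if comm_of[u] == comm_of[v]:
                assert w < tau
            else:
                assert w >= tau


class TestMad:
    @pytest.mark.parametrize(
        "values,expected",
        [((7, 7, 7), 0.0), ((5, 100, 110), 10.0), ((1, 2, 3, 4), 1.0)],
    )
    def test_hand_cases(self, values, expected):
        assert mad(values) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mad([])


class TestClassifyCommunities:
    def _three_community_setup(self):
        """Three single-vertex communities with sizes (5, 100, 110) and
        vertex means (0.9, 0.1, 0.15)."""
        sizes = (5, 100, 110)
        means = (0.9, 0.1, 0.15)
        offset = 0
        sets, attr = [], []
        for size, mean in zip(sizes, means):
            sets.append(set(range(offset, offset + size)))
            attr.extend([mean] * size)
            offset += size
        graph = toy_graph(sets, attr=attr)
        from tdahotspot import Community

        communities = [
            Community(
                vertex_ids=frozenset({i}),
                sample_ids=frozenset(sets[i]),
                attr_mean=means[i],
            )
            for i in range(3)
        ]
        return communities, graph

    def test_hand_worked_three_communities(self):
        """sigma2 = MAD(5,100,110) = 10; C1 is a hotspot (gap 0.775 > 0.5);
        C2 fails the gap test; C3 fails proportionality (105 - 110 < 10)."""
        communities, graph = self._three_community_setup()
        records = classify_communities(
            communities, graph, HotspotConfig(sigma1=3, epsilon=0.5, direction="both")
        )
        assert [r.sigma2 for r in records] == [10.0] * 3
        r1, r2, r3 = records
        assert r1.is_hotspot
        assert r1.neighbourhood_size == 210
        assert abs(0.9 - np.mean([0.1, 0.15])) == pytest.approx(0.775)
        assert not r2.is_hotspot
        assert r2.rejection_reason is RejectionReason.GAP_BELOW_EPSILON
        assert not r3.is_hotspot
        assert r3.rejection_reason is RejectionReason.NOT_PROPORTIONALLY_SMALL

    def test_single_community_is_degenerate(self):
        graph = toy_graph([{0, 1}], attr=[1.0, 1.0])
        communities = cut_dendrogram(single_linkage_on_graph(graph), graph)
        records = classify_communities(communities, graph, HotspotConfig(sigma1=1))
        assert records[0].rejection_reason is RejectionReason.DEGENERATE

    def test_size_floor_rejects_outliers(self):
        communities, graph = self._three_community_setup()
        records = classify_communities(
            communities, graph, HotspotConfig(sigma1=30, epsilon=0.5, direction="both")
        )
        assert records[0].rejection_reason is RejectionReason.TOO_SMALL

    def test_weighted_neighbourhood_mean_option(self):
        communities, graph = self._three_community_setup()
        records = classify_communities(
            communities, graph,
            HotspotConfig(sigma1=3, epsilon=0.5, direction="both"),
            weighted_neighbourhood=True,
        )
        # C1's neighbourhood weighted by member counts: (100*0.1 + 110*0.15)/210
        expected = (100 * 0.1 + 110 * 0.15) / 210
        assert records[0].neighbourhood_attr_mean == pytest.approx(expected)

    def test_direction_low_flips_the_gap_test(self):
        communities, graph = self._three_community_setup()
        records = classify_communities(
            communities, graph, HotspotConfig(sigma1=3, epsilon=0.5, direction="low")
        )
        assert not records[0].is_hotspot


def _planted_blob_graph(attr_high=1.0, seed=0):
    """Three well-separated blobs along the lens axis; the 40-sample blob
    carries the anomalous attribute."""
    rng = np.random.default_rng(seed)
    sizes = (40, 200, 200)
    centers = (0.0, 10.0, 20.0)
    rows, attr = [], []
    for cx, size in zip(centers, sizes):
        rows.append(rng.normal((cx, 0.0), 0.5, size=(size, 2)))
        attr.extend([attr_high if cx == 0.0 else 0.0] * size)
    values = np.vstack(rows)
    data = DataMatrix(
        values=values, sample_ids=tuple(f"s{i}" for i in range(len(values)))
    )
    return data, np.array(attr), set(range(40))


class TestDetectHotspots:
    def test_planted_hotspot_is_recovered(self):
        # one vertex per interval: each blob becomes one pure community
        data, attr, planted = _planted_blob_graph()
        clusterer = ClustererSpec(method="agglomerative", n_clusters=1)
        graph = build_mapper(data, data.values[:, 0], 8, 0.4, clusterer)
        records = detect_hotspots(
            graph, attr, HotspotConfig(sigma1=10, epsilon=0.5, direction="high")
        )
        hotspots = [r for r in records if r.is_hotspot]
        assert len(hotspots) == 1
        recovered = hotspots[0].community.sample_ids
        assert len(recovered & planted) / len(planted) >= 0.9

    def test_constant_attribute_yields_no_hotspot(self, ward6):
        data, _, _ = _planted_blob_graph()
        graph = build_mapper(data, data.values[:, 0], 8, 0.4, ward6)
        records = detect_hotspots(
            graph, np.ones(data.n_samples), HotspotConfig(sigma1=10, epsilon=0.5)
        )
        assert not any(r.is_hotspot for r in records)

    def test_epsilon_monotonicity(self, ward6):
        """Raising epsilon can only shrink the hotspot set."""
        data, attr, _ = _planted_blob_graph()
        graph = build_mapper(data, data.values[:, 0], 8, 0.4, ward6)
        previous = None
        for eps in (0.0, 0.2, 0.5, 0.8, 0.99):
            records = detect_hotspots(
                graph, attr, HotspotConfig(sigma1=5, epsilon=eps, direction="high")
            )
            hotspots = {
                frozenset(r.community.vertex_ids) for r in records if r.is_hotspot
            }
            if previous is not None:
                assert hotspots <= previous
            previous = hotspots

    def test_sigma1_monotonicity(self, ward6):
        data, attr, _ = _planted_blob_graph()
        graph = build_mapper(data, data.values[:, 0], 8, 0.4, ward6)
        previous = None
        for sigma1 in (1, 10, 30, 60, 500):
            records = detect_hotspots(
                graph, attr, HotspotConfig(sigma1=sigma1, epsilon=0.3, direction="high")
            )
            hotspots = {
                frozenset(r.community.vertex_ids) for r in records if r.is_hotspot
            }
            if previous is not None:
                assert hotspots <= previous
            previous = hotspots

    def test_communities_partition_vertices(self, ward6):
        data, attr, _ = _planted_blob_graph()
        graph = build_mapper(data, data.values[:, 0], 8, 0.4, ward6)
        records = detect_hotspots(graph, attr, HotspotConfig(sigma1=5, epsilon=0.3))
        counts = sum(len(r.community.vertex_ids) for r in records)
        assert counts == graph.n_vertices
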