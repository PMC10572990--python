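"""Interaction graph construction, subnetwork decomposition, centrality."""

import itertools
from collections import deque

import networkx as nx
import pandas as pd
import pytest

from lfqmarkers import (ConfigurationError, ValidationError,
                        build_marker_graph, decompose_subnetworks,
                        rank_centrality)
from lfqmarkers import io as lio
from lfqmarkers.network import normalize_confidences


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Enumerate all shortest paths by BFS path counting (graphs <= 12
    nodes) and accumulate pair dependencies per intermediate node."""
    nodes = list(graph.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # collect all shortest s-t paths explicitly
        dist = {s: 0}
        preds = {s: []}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    queue.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        if t not in dist:
            continue
        paths = []

        def unwind(v, acc):
            if v == s:
                paths.append(list(acc))
                return
            for u in preds[v]:
                unwind(u, acc + [u])

        unwind(t, [t])
        for path in paths:
            for inner in path[1:-1]:
                bc[inner] += 1.0 / len(paths)
    return bc


class TestBuildMarkerGraph:
    def test_threshold_boundary_inclusive(self):
        edges = edge_frame([("A", "B", 0.39), ("A", "C", 0.40)])
        g = build_marker_graph({"A", "B", "C"}, edges)
        assert set(g.graph.edges) == {("A", "C")}
        assert g.unmapped == {"B"}

    def test_string_score_scale_autodetected(self):
        edges = edge_frame([("A", "B", 700), ("A", "C", 350)])
        g = build_marker_graph({"A", "B", "C"}, edges, min_confidence=0.4)
        assert g.graph.edges[("A", "B")]["confidence"] == pytest.approx(0.7)
        assert ("A", "C") not in g.graph.edges

    def test_out_of_scale_confidence_rejected(self):
        with pytest.raises(ValidationError):
            build_marker_graph({"A", "B"}, edge_frame([("A", "B", 1500)]))

    def test_empty_edge_list_all_unmapped(self):
        g = build_marker_graph({"A", "B"}, edge_frame([]))
        assert len(g) == 0
        assert g.unmapped == {"A", "B"}

    def test_nonmarker_edges_excluded(self):
        edges = edge_frame([("A", "B", 0.9), ("A", "X", 0.9)])
        g = build_marker_graph({"A", "B"}, edges)
        assert set(g.nodes) == {"A", "B"}

    def test_duplicate_pairs_keep_highest_confidence(self):
        edges = edge_frame([("A", "B", 0.5), ("B", "A", 0.8)])
        g = build_marker_graph({"A", "B"}, edges)
        assert g.graph.edges[("A", "B")]["confidence"] == pytest.approx(0.8)

    def test_sixteen_markers_with_four_isolated_gives_twelve_nodes(self):
        """Marker sets typically exceed the mapped nodes: markers without a
        qualifying edge are reported unmapped, not drawn."""
        fx = lio.load_fixture("table1")
        markers = set(fx.proteins) | {"GhostA", "GhostB", "GhostC", "GhostD"}
        assert len(markers) == 16
        g = build_marker_graph(markers, fx.edges)
        assert len(g) == 12
        assert g.unmapped == {"GhostA", "GhostB", "GhostC", "GhostD"}

    def test_row_and_endpoint_order_invariance(self, rng):
        rows = [(f"N{i}", f"N{j}", 0.4 + 0.05 * ((i + j) % 10))
                for i in range(8) for j in range(i + 1, 8) if (i + j) % 3]
        edges = edge_frame(rows)
        flipped = edges.rename(columns={"protein_a": "protein_b",
                                        "protein_b": "protein_a"})
        shuffled = edges.sample(frac=1, random_state=0).reset_index(drop=True)
        markers = {f"N{i}" for i in range(8)}
        base = build_marker_graph(markers, edges)
        base_edges = {frozenset(e) for e in base.graph.edges}
        for variant in (flipped, shuffled):
            g = build_marker_graph(markers, variant)
            assert {frozenset(e) for e in g.graph.edges} == base_edges

    def test_raising_threshold_monotone_shrinkage(self):
        fx = lio.load_fixture("table2")
        prev_edges = None
        for thr in (0.4, 0.6, 0.8, 0.95):
            g = build_marker_graph(fx.proteins, fx.edges, min_confidence=thr)
            edges = {frozenset(e) for e in g.graph.edges}
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges


class TestDecomposeSubnetworks:
    def test_single_label_connected_graph_is_isolated(self):
        edges = edge_frame([("A", "B", 0.9), ("B", "C", 0.9)])
        g = build_marker_graph({"A", "B", "C"}, edges)
        (sub,) = decompose_subnetworks(g, dict.fromkeys("ABC", "only"))
        assert sub.members == {"A", "B", "C"}
        assert sub.isolated

    def test_unlabeled_node_is_named(self):
        g = build_marker_graph({"A", "B"}, edge_frame([("A", "B", 0.9)]))
        with pytest.raises(ConfigurationError, match="B"):
            decompose_subnetworks(g, {"A": "x"})

    def test_partition_sums_to_node_count(self, rng):
        fx = lio.load_fixture("table2")
        g = build_marker_graph(fx.proteins, fx.edges)
        subs = decompose_subnetworks(g, fx.category_map)
        assert sum(s.size for s in subs) == len(g)

    def test_matches_component_label_brute_force(self, rng):
        for trial in range(5):
            g_nx = nx.gnp_random_graph(10, 0.25, seed=trial)
            g_nx = nx.relabel_nodes(g_nx, {i: f"N{i}" for i in range(10)})
            edges = edge_frame([(u, v, 0.9) for u, v in g_nx.edges])
            labels = {f"N{i}": f"L{i % 3}" for i in range(10)}
            g = build_marker_graph(set(g_nx.nodes), edges)
            subs = decompose_subnetworks(g, labels)
            expected = {}
            for comp in nx.connected_components(g_nx):
                comp = frozenset(comp) & g.nodes
                if not comp:
                    continue
                for node in comp:
                    expected.setdefault((frozenset(comp), labels[node]),
                                        set()).add(node)
            assert {frozenset(s.members) for s in subs} == \
                {frozenset(v) for v in expected.values()}


class TestCentrality:
    def test_star_center_betweenness(self):
        edges = edge_frame([("C", leaf, 0.9) for leaf in "ABDE"])
        g = build_marker_graph({"A", "B", "C", "D", "E"}, edges)
        ranking = rank_centrality(g)
        assert ranking.iloc[0]["protein_id"] == "C"
        assert ranking.iloc[0]["betweenness"] == pytest.approx(6.0)
        assert ranking.iloc[0]["degree"] == 4

    def test_complete_graph_falls_back_to_name_order(self):
        nodes = ["D", "B", "A", "C"]
        edges = edge_frame([(u, v, 0.9)
                            for u, v in itertools.combinations(nodes, 2)])
        ranking = rank_centrality(build_marker_graph(set(nodes), edges))
        assert (ranking["betweenness"] == 0).all()
        assert list(ranking["protein_id"]) == ["A", "B", "C", "D"]

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_path_enumeration_oracle(self, trial):
        g_nx = nx.gnp_random_graph(11, 0.3, seed=trial)
        g_nx = nx.relabel_nodes(g_nx, {i: f"N{i}" for i in range(11)})
        edges = edge_frame([(u, v, 0.9) for u, v in g_nx.edges])
        g = build_marker_graph(set(g_nx.nodes), edges)
        ranking = rank_centrality(g)
        oracle = brute_force_betweenness(g.graph)
        for row in ranking.itertuples(index=False):
            assert row.betweenness == pytest.approx(oracle[row.protein_id],
                                                    abs=1e-9)


class TestPublishedMapFixtures:
    """The packaged marker tables with their synthetic-reconstruction edges
    reproduce the published map structure (counts from the marker tables;
    edges are reconstructions, not ground truth)."""

    def test_male_map(self):
        fx = lio.load_fixture("table1")
        g = build_marker_graph(fx.marker_set(), fx.edges)
        subs = decompose_subnetworks(g, fx.category_map)
        assert len(g) == 12
        comp_sizes = sorted(
            (sum(s.size for s in subs if s.component_id == c)
             for c in {s.component_id for s in subs}), reverse=True)
        assert comp_sizes == [10, 2]
        energy = next(s for s in subs if s.label == "Energy metabolism")
        assert energy.size == 2 and energy.isolated
        interconnected = sum(s.size for s in subs if not s.isolated)
        assert interconnected == 10
        assert rank_centrality(g).iloc[0]["protein_id"] == "Amph"

    def test_female_map(self):
        fx = lio.load_fixture("table2")
        g = build_marker_graph(fx.marker_set(), fx.edges)
        subs = decompose_subnetworks(g, fx.category_map)
        assert len(g) == 35
        by_label = {s.label: s.size for s in subs}
        assert by_label["Oxidative stress"] == 10
        assert by_label["Energy metabolism"] == 8
        comp_sizes = sorted(
            (sum(s.size for s in subs if s.component_id == c)
             for c in {s.component_id for s in subs}), reverse=True)
        assert comp_sizes == [31, 2, 2]
        isolated_labels = {s.label for s in subs if s.isolated}
        assert isolated_labels == {"Septin cytoskeleton", "Cell cycle"}
        top5 = set(rank_centrality(g).head(5)["protein_id"])
        assert {"Fkbp1a", "Hspa1b", "Eno2"} <= top5
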