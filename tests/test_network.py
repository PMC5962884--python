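"""Co-authorship graph construction, centralities, communities, exports.

Betweenness is checked against an exhaustive shortest-path-enumeration
oracle that never touches the library implementation.
"""

from itertools import combinations

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from fundingaudit.network import (betweenness_centrality, build_coauthor_graph,
                                  components, degree_centrality, export_graph,
                                  girvan_newman_partition, graph_stats,
                                  import_graph)
from fundingaudit.records import CorpusError
from fundingaudit.synth import generate_planted_graph

from conftest import make_record


# ---------------------------------------------------------------------------
# exhaustive oracle: enumerate every shortest path between every pair
# ---------------------------------------------------------------------------

def _all_shortest_paths(g, s, t):
    try:
        L = nx.shortest_path_length(g, s, t)
    except nx.NetworkXNoPath:
        return []
    paths = [[s]]
    for _ in range(L):
        # a prefix of len(p) nodes has len(p)-1 edges; appending n keeps it
        # on some shortest path iff len(p) + dist(n, t) == L
        paths = [p + [n] for p in paths for n in g.neighbors(p[-1])
                 if nx.has_path(g, n, t)
                 and len(p) + nx.shortest_path_length(g, n, t) == L]
    return [p for p in paths if p[-1] == t]


def oracle_betweenness(g, target):
    nodes = {n: 0.0 for n in g.nodes}
    edges = {tuple(sorted(e)): 0.0 for e in g.edges}
    for s, t in combinations(sorted(g.nodes), 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        frac = 1.0 / len(paths)
        for p in paths:
            for mid in p[1:-1]:
                nodes[mid] += frac
            for u, v in zip(p, p[1:]):
                edges[tuple(sorted((u, v)))] += frac
    return nodes if target == "nodes" else edges


class TestGraphConstruction:
    def test_single_record_makes_clique(self):
        g = build_coauthor_graph(
            [make_record("R1", ["A, X", "B, Y", "C, Z"])])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))

    def test_repeat_coauthorship_accumulates_weight(self):
        recs = [make_record("R1", ["A, X", "B, Y"]),
                make_record("R2", ["A, X", "B, Y"])]
        g = build_coauthor_graph(recs)
        (u, v, d), = g.edges(data=True)
        assert d["weight"] == 2

    def test_single_author_record_isolated_node(self):
        g = build_coauthor_graph([make_record("R1", ["Solo, A"])])
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_total_weight_equals_pair_sum_on_fixture(self, fixture_run):
        """Oracle: total edge weight is the direct sum of C(k,2) over
        records, k the number of distinct node keys on each byline."""
        from fundingaudit.names import normalize_name

        g = build_coauthor_graph(fixture_run.sample1)
        per_record = 0
        for rec in fixture_run.sample1:
            k = len({normalize_name(a).full_folded for a in rec.authors})
            per_record += k * (k - 1) // 2
        assert graph_stats(g)["total_edge_weight"] == per_record

    def test_fixture_component_count_matches_truth(self, fixture_run):
        cohort_clusters, assignment = (fixture_run.clusters,
                                       fixture_run.assignment)
        g = build_coauthor_graph(fixture_run.cohort.records, assignment)
        assert len(set(components(g).values())) == \
            fixture_run.truth.n_components["cohort"]


class TestDegree:
    def test_weighted_degree_and_handshake(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=3)
        g.add_edge("B", "C", weight=1)
        deg = degree_centrality(g)
        assert deg == {"A": 3.0, "B": 4.0, "C": 1.0}
        assert sum(deg.values()) == 2 * graph_stats(g)["total_edge_weight"]

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("A")
        assert degree_centrality(g)["A"] == 0.0


class TestBetweenness:
    def test_path_graph_values(self):
        g = nx.path_graph(["A", "B", "C"])
        nodes = betweenness_centrality(g, "nodes")
        edges = betweenness_centrality(g, "edges")
        assert nodes["B"] == 1.0 and nodes["A"] == 0.0
        assert edges[("A", "B")] == 2.0 and edges[("B", "C")] == 2.0

    def test_triangle_all_zero(self):
        g = nx.complete_graph(3)
        assert all(v == 0.0
                   for v in betweenness_centrality(g, "nodes").values())

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_equals_exhaustive_oracle_on_small_graphs(self, seed):
        import random

        rnd = random.Random(seed)
        n = rnd.randint(2, 8)
        g = nx.gnp_random_graph(n, rnd.uniform(0.3, 0.9), seed=seed)
        if not nx.is_connected(g):
            comp = list(nx.connected_components(g))
            for a, b in zip(comp, comp[1:]):
                g.add_edge(min(a), min(b))
        got_nodes = betweenness_centrality(g, "nodes")
        want_nodes = oracle_betweenness(g, "nodes")
        for k in g.nodes:
            assert got_nodes[k] == pytest.approx(want_nodes[k], abs=1e-9)
        got_edges = betweenness_centrality(g, "edges")
        want_edges = oracle_betweenness(g, "edges")
        for e in g.edges:
            key = e if e in got_edges else (e[1], e[0])
            assert got_edges[key] == pytest.approx(
                want_edges[tuple(sorted(e))], abs=1e-9)

    def test_isomorphism_invariance(self):
        g = nx.gnp_random_graph(7, 0.5, seed=4)
        relabel = {n: chr(ord("q") + n) for n in g.nodes}
        h = nx.relabel_nodes(g, relabel)
        bg = betweenness_centrality(g, "nodes")
        bh = betweenness_centrality(h, "nodes")
        for n in g.nodes:
            assert bg[n] == pytest.approx(bh[relabel[n]])


class TestGirvanNewman:
    def test_bridge_removed_first_and_partition(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                          (2, 3)], weight=1)
        part = girvan_newman_partition(g)
        assert part.removal_sequence[0] == (2, 3)
        comms = part.communities()
        assert sorted(map(sorted, comms)) == [[0, 1, 2], [3, 4, 5]]
        assert part.quality > 0

    def test_disconnected_cliques_partition_immediately(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = girvan_newman_partition(g)
        assert len(part.communities()) == 2

    def test_edgeless_graph(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        part = girvan_newman_partition(g)
        assert part.quality == 0.0
        assert len(set(part.assignment.values())) == 3

    def test_modularity_never_below_trivial(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        part = girvan_newman_partition(g)
        assert part.quality >= 0.0
        assert -0.5 <= part.quality <= 1.0

    def test_k_components_stop(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                          (2, 3)])
        part = girvan_newman_partition(g, stop="k_components", k_components=2)
        assert len(part.communities()) == 2
        assert len(part.removal_sequence) == 1

    def test_recovers_planted_two_block_partition(self):
        from sklearn.metrics import adjusted_rand_score

        g, labels = generate_planted_graph([20, 20], 0.6, 0.02, 0, seed=5)
        part = girvan_newman_partition(g)
        nodes = sorted(g.nodes)
        ari = adjusted_rand_score([labels[n] for n in nodes],
                                  [part.assignment[n] for n in nodes])
        assert ari >= 0.9


class TestComponentsAndExport:
    def test_components_deterministic_ids(self):
        g = nx.Graph()
        g.add_edges_from([("d", "c"), ("a", "b")])
        comp = components(g)
        assert comp["a"] == comp["b"] == 0
        assert comp["c"] == comp["d"] == 1

    def test_empty_graph(self):
        assert components(nx.Graph()) == {}

    def test_graphml_round_trip(self, tmp_path):
        g = build_coauthor_graph(
            [make_record("R1", ["A, X", "B, Y", "C, Z"])],
            node_labels=None)
        for n in g.nodes:
            g.nodes[n]["status"] = "unlisted_participating"
        part = girvan_newman_partition(g)
        p = tmp_path / "g.graphml"
        export_graph(g, p, part)
        back = import_graph(p)
        assert back.number_of_nodes() == 3 and back.number_of_edges() == 3
        for n, d in back.nodes(data=True):
            assert d["status"] == "unlisted_participating"
            assert "community" in d and "degree" in d
        assert all(d["weight"] == 1 for _, _, d in back.edges(data=True))

    def test_edgelist_export(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2)
        p = tmp_path / "g.tsv"
        export_graph(g, p, fmt="edgelist")
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert lines[1] == "a\tb\t2"

    def test_unknown_format_fatal(self, tmp_path):
        with pytest.raises(CorpusError):
            export_graph(nx.Graph(), tmp_path / "x", fmt="dot")
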