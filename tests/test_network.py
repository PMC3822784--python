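import itertools
import random

import networkx as nx
import pytest

from cointriage.cooccur import ConceptPair, extract_pairs
from cointriage.network import (
    CooccurrenceNetwork,
    PageRankConvergenceError,
    betweenness,
    build_network,
    pagerank,
    write_centrality_csv,
    write_edgelist_tsv,
    write_graphml,
)

from conftest import make_doc


def _bfs_dist(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj, dist, s, t):
    """All shortest s-t paths by walking the BFS distance field backwards."""
    if t not in dist:
        return []
    paths = []

    def extend(node, acc):
        if node == s:
            paths.append([s] + acc)
            return
        for u in adj[node]:
            if u in dist and dist[u] == dist[node] - 1:
                extend(u, [node] + acc)

    extend(t, [])
    return paths


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: hand-rolled BFS over every vertex pair,
    explicit enumeration of all shortest paths, fractional pass-through
    credit per interior vertex."""
    adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
    bet = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        dist = _bfs_dist(adj, s)
        paths = _all_shortest_paths(adj, dist, s, t)
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def net_of(g: nx.Graph) -> CooccurrenceNetwork:
    return CooccurrenceNetwork(graph=g)


def cd(a, b):
    return ConceptPair.make(a, "chemical", b, "disease")


class TestBuildNetwork:
    def test_shared_pair_creates_typed_edge(self):
        docs = {
            "A": extract_pairs(make_doc("A", ("c1", "d1"))),
            "B": extract_pairs(make_doc("B", ("c1", "d1"))),
        }
        net = build_network(docs)
        assert net.vertices == {"A", "B"}
        assert net.edge_types("A", "B") == {"cd"}
        assert net.shared_pairs("A", "B") == {cd("c1", "d1")}

    def test_different_pairs_no_edge(self):
        docs = {
            "A": extract_pairs(make_doc("A", ("c1", "d1"))),
            "B": extract_pairs(make_doc("B", ("c1", "d2"))),
        }
        net = build_network(docs)
        assert net.n_edges() == 0
        assert net.vertices == {"A", "B"}  # isolated vertices retained

    def test_same_type_rule_relaxes_edges(self):
        docs = {
            "A": extract_pairs(make_doc("A", ("c1", "d1"))),
            "B": extract_pairs(make_doc("B", ("c1", "d2"))),
        }
        net = build_network(docs, edge_rule="same_type")
        assert net.n_edges() == 1
        assert net.edge_types("A", "B") == {"cd"}

    def test_three_docs_sharing_pair_form_triangle(self):
        docs = {d: extract_pairs(make_doc(d, ("c1", "g1"))) for d in "ABC"}
        net = build_network(docs)
        assert net.n_edges() == 3
        for a, b in itertools.combinations("ABC", 2):
            assert net.edge_types(a, b) == {"cg"}

    def test_no_self_loops_and_symmetric(self):
        docs = {d: extract_pairs(make_doc(d, ("c1", "d1"), ("c1", "d1")))
                for d in "AB"}
        net = build_network(docs)
        assert not any(a == b for a, b in net.graph.edges)
        assert net.graph.has_edge("B", "A")

    def test_invariant_to_document_order(self):
        specs = {"A": ("c1", "d1"), "B": ("c1", "d1"), "C": ("c2", "g1")}
        pairs = {d: extract_pairs(make_doc(d, s)) for d, s in specs.items()}
        net1 = build_network(dict(pairs))
        net2 = build_network(dict(reversed(list(pairs.items()))))
        assert set(map(frozenset, net1.graph.edges)) == set(map(frozenset, net2.graph.edges))


class TestBetweenness:
    def test_path_graph_interior_vertex(self):
        g = nx.path_graph(["a", "b", "c"])
        assert betweenness(net_of(g)) == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_toy_network_hub_vertices(self, toy_network):
        bet = betweenness(toy_network)
        assert bet == {"P1": 0.0, "P2": 3.0, "P3": 0.0, "P4": 3.0, "P5": 0.0}

    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, four leaves -> 6 leaf pairs
        assert betweenness(net_of(g))[0] == pytest.approx(6.0)

    def test_complete_graph_all_zero(self):
        g = nx.complete_graph(5)
        assert all(v == 0.0 for v in betweenness(net_of(g)).values())

    def test_vertex_transitive_graph_equal_values(self):
        g = nx.cycle_graph(6)
        values = set(betweenness(net_of(g)).values())
        assert len(values) == 1

    def test_matches_brute_force_on_random_graphs(self):
        """200 Erdős–Rényi graphs of ≤ 8 vertices, including disconnected
        ones, against independent all-shortest-paths enumeration."""
        rng = random.Random(20260925)
        for trial in range(200):
            n = rng.randint(2, 8)
            p = rng.uniform(0.1, 0.9)
            g = nx.gnp_random_graph(n, p, seed=rng.randrange(2**31))
            expected = brute_force_betweenness(g)
            got = betweenness(net_of(g))
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9), (trial, v)


class TestPageRank:
    def test_toy_network_printed_values(self, toy_network):
        pr = pagerank(toy_network, d=0.85)
        assert round(pr["P2"], 2) == 0.29
        assert round(pr["P4"], 2) == 0.29
        assert round(pr["P3"], 2) == 0.19
        assert round(pr["P1"], 2) == 0.11
        assert round(pr["P5"], 2) == 0.11
        assert pr["P1"] == pytest.approx(pr["P5"], abs=1e-9)

    @pytest.mark.parametrize("d", [0.15, 0.5, 0.85])
    def test_single_edge_symmetry(self, d):
        g = nx.Graph([("a", "b")])
        pr = pagerank(net_of(g), d=d)
        assert pr["a"] == pytest.approx(0.5, abs=1e-9)
        assert pr["b"] == pytest.approx(0.5, abs=1e-9)

    def test_triangle_uniform(self):
        pr = pagerank(net_of(nx.complete_graph(3)))
        assert all(v == pytest.approx(1 / 3, abs=1e-9) for v in pr.values())

    def test_regular_graph_uniform(self):
        g = nx.cycle_graph(7)
        pr = pagerank(net_of(g))
        assert all(v == pytest.approx(1 / 7, abs=1e-9) for v in pr.values())

    def test_sums_to_one_with_isolated_vertices(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_nodes_from(["lone1", "lone2"])
        pr = pagerank(net_of(g))
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-6)
        # isolated vertices share the same (positive) score
        assert pr["lone1"] == pytest.approx(pr["lone2"], abs=1e-12)
        assert pr["lone1"] >= (1 - 0.85) / 5

    def test_every_vertex_at_least_teleport_mass(self):
        rng = random.Random(3)
        for _ in range(20):
            g = nx.gnp_random_graph(rng.randint(2, 10), 0.3, seed=rng.randrange(2**31))
            pr = pagerank(net_of(g))
            n = g.number_of_nodes()
            assert all(v >= (1 - 0.85) / n - 1e-12 for v in pr.values())
            assert sum(pr.values()) == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_independent_implementation(self):
        rng = random.Random(11)
        for _ in range(20):
            g = nx.gnp_random_graph(rng.randint(2, 12), 0.35, seed=rng.randrange(2**31))
            mine = pagerank(net_of(g), tol=1e-12)
            ref = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=500)
            for v in g.nodes:
                assert mine[v] == pytest.approx(ref[v], abs=1e-8)

    def test_nonconvergence_reports_residual(self, toy_network):
        with pytest.raises(PageRankConvergenceError, match="residual"):
            pagerank(toy_network, tol=1e-15, max_iter=2)

    def test_invalid_damping_rejected(self, toy_network):
        with pytest.raises(ValueError, match="damping"):
            pagerank(toy_network, d=1.5)

    def test_empty_network(self):
        assert pagerank(net_of(nx.Graph())) == {}


class TestExports:
    def test_edgelist_and_centrality_files(self, tmp_path, toy_network):
        docs = {
            "A": extract_pairs(make_doc("A", ("c1", "d1"))),
            "B": extract_pairs(make_doc("B", ("c1", "d1"))),
        }
        net = build_network(docs)
        edge_path = tmp_path / "edges.tsv"
        write_edgelist_tsv(net, edge_path)
        lines = edge_path.read_text().splitlines()
        assert lines[0] == "doc_a\tdoc_b\ttypes\tn_shared_pairs"
        assert lines[1] == "A\tB\tcd\t1"

        bet = betweenness(net)
        pr = pagerank(net)
        cent_path = tmp_path / "centrality.csv"
        write_centrality_csv(bet, pr, cent_path)
        assert cent_path.read_text().splitlines()[0] == "doc_id,betweenness,pagerank"

        gml_path = tmp_path / "net.graphml"
        write_graphml(net, gml_path)
        back = nx.read_graphml(gml_path)
        assert set(back.nodes) == {"A", "B"}
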