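"""Network construction, topology/centrality metrics and I/O round-trips."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from distortnet import (
    AssociationConfig,
    DistortionTaxonomy,
    adjacency_metrics,
    build_network,
    centralities,
    read_network,
    top_hubs,
    topology,
    write_network,
)
from distortnet.network import DistortionNetwork, hubs_from_graph

from conftest import oracle_density_clustering


def pair_table(edges, lift=1.5):
    rows = [
        {
            "label_i": u, "label_j": v,
            "lift": (lift if np.isscalar(lift) else lift[i]),
            "observed": 5, "p_value": 1e-6,
        }
        for i, (u, v) in enumerate(edges)
    ]
    return pd.DataFrame(rows)


def graph_network(g: nx.Graph, lift=1.5) -> DistortionNetwork:
    edges = [(str(u), str(v)) for u, v in g.edges]
    return build_network(pair_table(edges, lift))


class TestBuild:
    def test_edges_carry_attributes(self):
        net = build_network(pair_table([("A", "B")], lift=2.0))
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.graph["A"]["B"]["lift"] == 2.0
        assert net.graph["A"]["B"]["observed"] == 5

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network(pair_table([("A", "B"), ("B", "A")]))

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            build_network(pair_table([("A", "A")]))

    def test_keep_policy_includes_isolates(self):
        tax = DistortionTaxonomy(("A", "B", "C"))
        net = build_network(pair_table([("A", "B")]), isolate_policy="keep", taxonomy=tax)
        assert net.n_nodes == 3

    def test_empty_input_drop_policy(self):
        net = build_network(pair_table([]))
        assert net.n_nodes == 0 and net.n_edges == 0


class TestTopology:
    def test_complete_graph(self):
        rep = topology(graph_network(nx.complete_graph(5)))
        assert rep.density == pytest.approx(1.0)
        assert rep.avg_clustering == pytest.approx(1.0)

    def test_density_13_nodes_35_edges(self):
        g = nx.gnm_random_graph(13, 35, seed=1)
        rep = topology(graph_network(g))
        assert rep.density == pytest.approx(35 / 78)
        assert round(rep.density, 3) == 0.449

    def test_star_graph_disassortative(self):
        rep = topology(graph_network(nx.star_graph(6)))
        assert rep.assortativity is not None and rep.assortativity < 0

    def test_regular_graph_assortativity_missing(self):
        rep = topology(graph_network(nx.cycle_graph(6)))
        assert rep.assortativity is None

    def test_degree_sum_is_twice_edges(self):
        g = nx.gnm_random_graph(10, 20, seed=2)
        net = graph_network(g)
        rep = centralities(net)
        assert sum(rep.degree.values()) == 2 * net.n_edges


class TestCentralities:
    def test_path_graph_betweenness(self):
        rep = centralities(graph_network(nx.path_graph(3)))
        assert rep.betweenness["1"] == pytest.approx(1.0)
        assert rep.degree["1"] == 2

    def test_closed_neighbors_give_unit_clustering(self):
        rep = centralities(graph_network(nx.complete_graph(3)))
        assert all(c == pytest.approx(1.0) for c in rep.local_clustering.values())

    def test_uniform_weights_match_unweighted_betweenness(self):
        g = nx.gnm_random_graph(12, 30, seed=3)
        rep = centralities(graph_network(g, lift=1.7))
        unweighted = nx.betweenness_centrality(g, normalized=True)
        for node, b in unweighted.items():
            assert rep.betweenness[str(node)] == pytest.approx(b, abs=1e-12)

    def test_weighted_degree_sums_incident_lifts(self):
        net = build_network(pair_table([("A", "B"), ("A", "C")], lift=[2.0, 3.0]))
        rep = centralities(net)
        assert rep.weighted_degree["A"] == pytest.approx(5.0)

    def test_cycle_betweenness_closed_form(self):
        # C5: each node lies on 1 of the C(4,2)=6 pair paths as interior -> 1/6
        rep = centralities(graph_network(nx.cycle_graph(5)))
        for b in rep.betweenness.values():
            assert b == pytest.approx(1 / 6)


class TestHubs:
    def test_tie_breaking_rule(self):
        from distortnet.network import CentralityReport

        rep = CentralityReport(
            density=0.0, avg_clustering=0.0, transitivity=0.0, assortativity=None,
            degree={"a": 10, "b": 8, "c": 8, "d": 8, "e": 1},
            weighted_degree={"a": 12.0, "b": 5.0, "c": 7.0, "d": 7.0, "e": 1.0},
        )
        # degree first, then weighted degree, then label lexicographic (c/d tie)
        assert top_hubs(rep, 4) == ["a", "c", "d", "b"]

    def test_k_larger_than_node_count_returns_all(self):
        net = build_network(pair_table([("A", "B")]))
        rep = centralities(net)
        assert set(top_hubs(rep, 10)) == {"A", "B"}

    def test_hubs_from_graph_matches_report_path(self):
        g = nx.gnm_random_graph(9, 14, seed=4)
        net = graph_network(g)
        assert hubs_from_graph(net, 5) == top_hubs(centralities(net), 5)


class TestAdjacencyMetrics:
    def test_matches_networkx_on_random_graphs(self, rng):
        """The vectorised hot-loop metrics equal the networkx definitions."""
        for _ in range(30):
            n = int(rng.integers(3, 12))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)), seed=int(rng.integers(1e6)))
            adj = nx.to_numpy_array(g) > 0
            d, c = adjacency_metrics(adj, drop_isolates=False)
            assert d == pytest.approx(nx.density(g), abs=1e-12)
            assert c == pytest.approx(nx.average_clustering(g), abs=1e-12)

    def test_matches_brute_force_exhaustively_on_4_nodes(self):
        """All 64 graphs on 4 nodes agree with triangle-enumeration oracle."""
        import itertools

        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for bits in itertools.product([0, 1], repeat=6):
            adj = np.zeros((4, 4), dtype=bool)
            for (i, j), b in zip(pairs, bits):
                adj[i, j] = adj[j, i] = bool(b)
            d, c = adjacency_metrics(adj, drop_isolates=False)
            od, oc = oracle_density_clustering(adj)
            assert d == pytest.approx(od, abs=1e-12)
            assert c == pytest.approx(oc, abs=1e-12)


class TestIO:
    @pytest.mark.parametrize("fmt", ["graphml", "edge_csv", "json_report"])
    def test_round_trip(self, tmp_path, fmt):
        g = nx.gnm_random_graph(8, 12, seed=5)
        net = graph_network(g, lift=1.9)
        suffix = {"graphml": "graphml", "edge_csv": "csv", "json_report": "json"}[fmt]
        path = tmp_path / f"net.{suffix}"
        write_network(net, path, format=fmt)
        back = read_network(path, format=fmt)
        assert set(back.graph.edges) == set(
            (str(u), str(v)) for u, v in net.graph.edges
        ) or nx.is_isomorphic(back.graph, net.graph)
        for u, v, d in net.graph.edges(data=True):
            assert back.graph[str(u)][str(v)]["lift"] == pytest.approx(d["lift"])

    def test_empty_network_round_trip(self, tmp_path):
        net = build_network(pair_table([]))
        write_network(net, tmp_path / "empty.json", format="json_report")
        back = read_network(tmp_path / "empty.json")
        assert back.n_edges == 0

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network(pair_table([("A", "B")]))
        with pytest.raises(ValueError):
            write_network(net, tmp_path / "x.bin", format="parquet")
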