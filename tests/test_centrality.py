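import math

import networkx as nx
import numpy as np
import pytest

from netpharm.centrality import (
    FEATURES,
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    local_average_connectivity,
    network_centrality,
)
from netpharm.errors import ValidationError

from oracles import CENTRALITY_ORACLES, connected_atlas


class TestClosedForms:
    def test_triangle_is_fully_symmetric(self):
        g = nx.complete_graph(3)
        assert all(v == 0.0 for v in betweenness_centrality(g).values())
        assert all(v == 1.0 for v in closeness_centrality(g).values())
        assert all(v == 2.0 for v in degree_centrality(g).values())
        ec = eigenvector_centrality(g)
        assert all(math.isclose(v, 1 / math.sqrt(3)) for v in ec.values())
        assert all(v == 1.0 for v in local_average_connectivity(g).values())
        assert all(v == 2.0 for v in network_centrality(g).values())

    def test_three_node_path(self):
        g = nx.path_graph(3)  # 0 - 1 - 2
        assert betweenness_centrality(g) == {0: 0.0, 1: 1.0, 2: 0.0}
        cc = closeness_centrality(g)
        assert cc[1] == 1.0 and math.isclose(cc[0], 2 / 3)
        assert local_average_connectivity(g)[1] == 0.0

    def test_star_eigenvector_closed_form(self):
        g = nx.star_graph(3)  # center 0, three leaves
        ec = eigenvector_centrality(g)
        assert math.isclose(ec[0], 1 / math.sqrt(2), rel_tol=1e-9)
        for leaf in (1, 2, 3):
            assert math.isclose(ec[leaf], 1 / math.sqrt(6), rel_tol=1e-9)

    def test_tree_has_zero_network_centrality(self):
        g = nx.random_labeled_tree(12, seed=5)
        assert set(network_centrality(g).values()) == {0.0}

    def test_cycle_constant_vectors(self):
        g = nx.cycle_graph(5)
        table = centrality_table(g).frame
        for feature in FEATURES:
            assert table[feature].nunique() == 1

    def test_component_restricted_closeness(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"),
                      ("X", "Y"), ("Y", "Z"), ("X", "Z")])
        assert set(closeness_centrality(g).values()) == {1.0}


class TestCliquePendantFixture:
    def test_hand_derived_values(self, clique_pendant):
        table = centrality_table(clique_pendant).frame
        for i in range(5):
            clique, leaf = f"C{i}", f"L{i}"
            assert table.loc[clique, "bc"] == pytest.approx(8.0)
            assert table.loc[clique, "dc"] == 5.0
            assert table.loc[clique, "lac"] == pytest.approx(12 / 5)
            assert table.loc[clique, "nc"] == pytest.approx(3.0)
            assert table.loc[clique, "cc"] == pytest.approx(9 / 13)
            assert table.loc[leaf, "bc"] == 0.0
            assert table.loc[leaf, "dc"] == 1.0
            assert table.loc[leaf, "lac"] == 0.0
            assert table.loc[leaf, "nc"] == 0.0
            assert table.loc[leaf, "cc"] == pytest.approx(9 / 21)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_nodes", [2, 3, 4, 5, 6])
    def test_all_connected_graphs_match_bruteforce(self, n_nodes):
        graphs = [
            g for g in connected_atlas(max_nodes=6)
            if g.number_of_nodes() == n_nodes
        ]
        table_fn = centrality_table
        for g in graphs:
            frame = table_fn(g).frame
            for feature, oracle in CENTRALITY_ORACLES.items():
                expected = oracle(g)
                for node in g:
                    assert frame.loc[node, feature] == pytest.approx(
                        expected[node], abs=1e-8
                    ), (feature, sorted(g.edges))

    def test_random_graph_degree_is_adjacency_row_sum(self):
        g = nx.gnp_random_graph(8, 0.4, seed=2)
        a = nx.to_numpy_array(g, nodelist=sorted(g))
        dc = degree_centrality(g)
        assert [dc[v] for v in sorted(g)] == a.sum(axis=1).tolist()

    def test_random_graph_eigenvector_matches_dense_solver(self):
        g = nx.gnp_random_graph(8, 0.5, seed=7)
        assert nx.is_connected(g)
        ec = eigenvector_centrality(g)
        expected = CENTRALITY_ORACLES["ec"](g)
        assert max(abs(ec[v] - expected[v]) for v in g) < 1e-8


class TestInvariantsAndEdgeCases:
    def test_ec_unit_euclidean_norm(self):
        g = nx.gnp_random_graph(20, 0.2, seed=9)
        g.remove_nodes_from(list(nx.isolates(g)))
        ec = eigenvector_centrality(g)
        assert math.isclose(sum(v * v for v in ec.values()), 1.0, rel_tol=1e-9)
        assert all(v >= 0 for v in ec.values())

    def test_edgeless_graph_ec_is_zero_in_table(self):
        g = nx.empty_graph(3)
        table = centrality_table(g).frame
        assert (table["ec"] == 0.0).all()
        with pytest.raises(ValidationError):
            eigenvector_centrality(g)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            centrality_table(nx.Graph())

    def test_adding_edge_never_decreases_endpoint_degree(self):
        g = nx.gnp_random_graph(10, 0.3, seed=1)
        non_edges = list(nx.non_edges(g))
        before = degree_centrality(g)
        u, v = non_edges[0]
        g.add_edge(u, v)
        after = degree_centrality(g)
        assert after[u] == before[u] + 1 and after[v] == before[v] + 1

    def test_normalized_scales(self):
        g = nx.gnp_random_graph(9, 0.4, seed=3)
        raw = centrality_table(g).frame
        norm = centrality_table(g, normalized=True).frame
        n = g.number_of_nodes()
        assert np.allclose(norm["bc"], raw["bc"] / ((n - 1) * (n - 2) / 2))
        assert np.allclose(norm["dc"], raw["dc"] / (n - 1))
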