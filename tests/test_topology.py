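"""Node metrics and network summary against closed forms, the exhaustive
path-enumeration oracle, and networkx as an independent cross-check."""

import networkx as nx
import numpy as np
import pytest

from afirnet import topology
from afirnet.synthetic import fixture, fixture_names
from conftest import net_from_edges, oracle_metrics, random_connected_network


class TestClosedForms:
    """Every closed-form metric bundled with the named fixtures must match exactly."""

    @pytest.mark.parametrize("name", fixture_names())
    def test_fixture_expected_values(self, name):
        net, expected = fixture(name)
        sp = topology.all_pairs_shortest_paths(net)
        metrics = topology.compute_node_metrics(net, sp)
        summary = topology.network_summary(net, sp)
        column_for = {
            "betweenness": "betweenness",
            "closeness": "closeness",
            "stress": "stress",
            "eccentricity": "eccentricity",
            "radiality": "radiality",
            "neighborhood_connectivity": "neighborhood_connectivity",
            "topological_coefficient": "topological_coefficient",
            "clustering_coefficient": "clustering_coefficient",
        }
        for key, col in column_for.items():
            for node, want in expected.get(key, {}).items():
                assert metrics.loc[node, col] == pytest.approx(want, abs=1e-12), (
                    f"{name}: {col}({node})"
                )
        for key, attr in [
            ("num_nodes", "num_nodes"), ("diameter", "diameter"),
            ("characteristic_path_length", "characteristic_path_length"),
            ("avg_neighbors", "avg_neighbors"),
        ]:
            if key in expected:
                assert getattr(summary, attr) == pytest.approx(expected[key])

    def test_c4_opposite_corners_have_two_shortest_paths(self):
        net, expected = fixture("C4")
        sp = topology.all_pairs_shortest_paths(net)
        i, j = sp.index["n0"], sp.index["n2"]
        assert sp.dist[i, j] == expected["dist_opposite"]
        assert sp.sigma[i, j] == expected["sigma_opposite"]

    def test_p3_sigma_through_center(self):
        net, _ = fixture("P3")
        sp = topology.all_pairs_shortest_paths(net)
        assert sp.dist[sp.index["n0"], sp.index["n2"]] == 2
        assert sp.sigma[sp.index["n0"], sp.index["n2"]] == 1
        assert sp.sigma_through("n0", "n2", "n1") == 1

    def test_clustering_formula_direct(self):
        # hub n with neighbors a, b, c; only a-b linked: CI = 2*1/(3*2)
        net = net_from_edges([("n", "a"), ("n", "b"), ("n", "c"), ("a", "b")])
        assert topology.node_clustering(net, "n") == pytest.approx(1 / 3)

    def test_s4_leaf_closeness(self):
        net, _ = fixture("S4")
        close = topology.closeness_centrality(net)
        assert close["n1"] == pytest.approx(0.6)
        assert close["n0"] == pytest.approx(1.0)


class TestOracleEquivalence:
    """BFS path counting and every path-derived metric agree with exhaustive
    simple-path enumeration on 100 seeded random connected graphs."""

    SEEDS = range(100)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_enumeration(self, seed):
        net = random_connected_network(seed)
        oracle = oracle_metrics(net)
        sp = topology.all_pairs_shortest_paths(net)
        for (s, t), d in oracle["dist"].items():
            assert sp.dist[sp.index[s], sp.index[t]] == d
            assert sp.sigma[sp.index[s], sp.index[t]] == oracle["sigma"][(s, t)]
        bet = topology.betweenness_centrality(net, sp)
        close = topology.closeness_centrality(net, sp)
        stress = topology.stress_centrality(net, sp)
        for n in net.nodes:
            assert bet[n] == pytest.approx(oracle["betweenness"][n], abs=1e-9)
            assert close[n] == pytest.approx(oracle["closeness"][n], abs=1e-9)
            assert stress[n] == oracle["stress"][n]

    def test_cross_check_against_networkx(self):
        """Independent library route: on connected graphs our betweenness and
        closeness equal networkx's (same normalization there)."""
        for seed in range(20):
            net = random_connected_network(seed + 1000)
            bet = topology.betweenness_centrality(net)
            close = topology.closeness_centrality(net)
            nx_bet = nx.betweenness_centrality(net.graph, normalized=True)
            nx_close = nx.closeness_centrality(net.graph)
            for n in net.nodes:
                assert bet[n] == pytest.approx(nx_bet[n], abs=1e-9)
                assert close[n] == pytest.approx(nx_close[n], abs=1e-9)


class TestInvariants:
    def test_centralities_bounded_and_leaves_score_zero(self):
        for seed in (0, 7, 21):
            net = random_connected_network(seed)
            m = topology.compute_node_metrics(net)
            assert ((m["betweenness"] >= 0) & (m["betweenness"] <= 1)).all()
            assert ((m["closeness"] >= 0) & (m["closeness"] <= 1)).all()
            leaves = m.index[m["degree"] == 1]
            assert (m.loc[leaves, "betweenness"] == 0).all()

    def test_relabeling_invariance(self):
        net = random_connected_network(42)
        rng = np.random.default_rng(0)
        perm = dict(zip(net.nodes, rng.permutation(net.nodes)))
        relabeled = net_from_edges(
            (perm[r.source], perm[r.target]) for r in net.edge_records
        )
        m1 = topology.compute_node_metrics(net)
        m2 = topology.compute_node_metrics(relabeled)
        for n in net.nodes:
            np.testing.assert_allclose(
                m1.loc[n].to_numpy(), m2.loc[perm[n]].to_numpy(), atol=1e-9
            )

    def test_summary_consistency(self, afirnet_like_net):
        s = topology.network_summary(afirnet_like_net)
        assert s.characteristic_path_length <= s.diameter
        assert s.avg_neighbors == pytest.approx(
            2 * afirnet_like_net.num_simple_edges / s.num_nodes
        )

    def test_unreachable_pairs_stay_within_components(self):
        """A two-component network averages distances inside components only."""
        joint = net_from_edges(
            [("a", "b"), ("b", "c"),  # P3
             ("x", "y"), ("y", "z"), ("z", "x")]  # K3
        )
        m = topology.compute_node_metrics(joint)
        p3, _ = fixture("P3")
        k3, _ = fixture("K3")
        mp3 = topology.compute_node_metrics(p3)
        mk3 = topology.compute_node_metrics(k3)
        np.testing.assert_allclose(
            m.loc[["a", "b", "c"]].to_numpy(), mp3.to_numpy(), atol=1e-9
        )
        np.testing.assert_allclose(
            m.loc[["x", "y", "z"]].to_numpy(), mk3.to_numpy(), atol=1e-9
        )
        s = topology.network_summary(joint)
        assert s.connected_components == 2
        # CPL pools connected pairs from both components: (3*(4/3) + 3*1) / 6
        assert s.characteristic_path_length == pytest.approx(7 / 6)


class TestPropertyBased:
    """Structural invariants over arbitrary small edge lists."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    edge_lists = st.lists(
        st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=15
    )

    @given(edges=edge_lists)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_distance_and_sigma_symmetry(self, edges):
        net = net_from_edges((f"n{u}", f"n{v}") for u, v in edges if u != v)
        if net.num_nodes == 0:
            return
        sp = topology.all_pairs_shortest_paths(net)
        np.testing.assert_array_equal(sp.dist, sp.dist.T)
        np.testing.assert_array_equal(sp.sigma, sp.sigma.T)

    @given(edges=edge_lists)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_degree_sum_is_twice_edge_count(self, edges):
        net = net_from_edges((f"n{u}", f"n{v}") for u, v in edges if u != v)
        if net.num_nodes == 0:
            return
        m = topology.compute_node_metrics(net)
        assert m["degree"].sum() == 2 * net.num_simple_edges
        s = topology.network_summary(net)
        assert s.avg_neighbors == pytest.approx(
            2 * net.num_simple_edges / net.num_nodes
        )


class TestSummaryOptions:
    def test_empty_network_rejected(self):
        from afirnet.netio import MolecularNetwork

        with pytest.raises(ValueError):
            topology.network_summary(MolecularNetwork([]))

    def test_clustering_average_convention(self):
        # P3: CI = (0, 0, 0) over all nodes; degree>=2 restriction averages only n1
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        all_nodes = topology.network_summary(net).network_clustering_coefficient
        deg2 = topology.network_summary(
            net, clustering_min_degree=2
        ).network_clustering_coefficient
        # a, b, c form a triangle, d dangles off c
        assert all_nodes == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)
        assert deg2 == pytest.approx((1 + 1 + 1 / 3) / 3)

    def test_isolated_node_conventions(self):
        net = net_from_edges([("a", "b")], nodes=["loner"])
        m = topology.compute_node_metrics(net)
        assert m.loc["loner"].tolist() == [0.0] * 10
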