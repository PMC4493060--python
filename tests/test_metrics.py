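import numpy as np
import pytest

from netreconfig import (
    Network,
    UndefinedMetricError,
    char_path_length,
    clustering,
    degree_stats,
    global_efficiency,
    local_efficiency,
    modularity,
    nodal_efficiency,
    physical_distance,
    shortest_paths,
    weighted_metric_suite,
)
from netreconfig.metrics import global_metrics

from _oracles import (
    brute_char_path_length,
    brute_clustering,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    exhaustive_max_modularity,
    floyd_warshall,
    modularity_of_partition,
    random_binary_adjacency,
)
from conftest import binary_net, net_from_edges


class TestDegree:
    def test_complete_graph(self, complete4):
        k, deg = degree_stats(complete4)
        assert k == 3.0 and np.all(deg == 3)

    def test_empty_graph(self):
        k, _ = degree_stats(binary_net(np.zeros((5, 5))))
        assert k == 0.0

    def test_two_triangles_with_bridge(self):
        net = net_from_edges(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])
        k, _ = degree_stats(net)
        assert k == pytest.approx(2 * 7 / 6)


class TestClustering:
    def test_complete_graph(self, complete4):
        cp, c = clustering(complete4)
        assert cp == 1.0 and np.all(c == 1.0)

    def test_path_has_no_triangles(self, path4):
        assert clustering(path4)[0] == 0.0

    def test_triangle_plus_pendant(self, triangle_pendant):
        cp, c = clustering(triangle_pendant)
        np.testing.assert_allclose(c, [1 / 3, 1.0, 1.0, 0.0])
        assert cp == pytest.approx(7 / 12)


class TestPaths:
    def test_complete_graph_distance_one(self, complete4):
        d = shortest_paths(complete4).d
        assert np.all(d[~np.eye(4, dtype=bool)] == 1.0)

    def test_path_end_to_end(self, path4):
        assert shortest_paths(path4).d[0, 3] == 3.0

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            a = random_binary_adjacency(rng, n, rng.uniform(0.1, 0.9))
            d = shortest_paths(binary_net(a)).d
            np.testing.assert_array_equal(d, floyd_warshall(a))


class TestCharPathLength:
    def test_complete_graph(self, complete4):
        assert char_path_length(shortest_paths(complete4)) == 1.0

    def test_path4(self, path4):
        assert char_path_length(shortest_paths(path4)) == pytest.approx(10 / 6)

    def test_disconnected_uses_finite_pairs_only(self):
        net = net_from_edges(4, [(0, 1), (2, 3)])
        paths = shortest_paths(net)
        assert char_path_length(paths) == 1.0
        assert paths.reachable_fraction == pytest.approx(2 / 6)

    def test_empty_graph_undefined(self):
        with pytest.raises(UndefinedMetricError):
            char_path_length(shortest_paths(binary_net(np.zeros((4, 4)))))


class TestEfficiency:
    def test_global_complete(self, complete4):
        assert global_efficiency(shortest_paths(complete4)) == 1.0

    def test_global_path4(self, path4):
        assert global_efficiency(shortest_paths(path4)) == pytest.approx(13 / 18)

    def test_global_empty(self):
        assert global_efficiency(shortest_paths(binary_net(np.zeros((5, 5))))) == 0.0

    def test_local_complete(self, complete4):
        assert local_efficiency(complete4)[0] == 1.0

    def test_local_star_is_zero(self, star4):
        assert local_efficiency(star4)[0] == 0.0

    def test_local_matches_brute_force(self, triangle_pendant, rng):
        assert local_efficiency(triangle_pendant)[0] == pytest.approx(
            brute_local_efficiency(triangle_pendant.adjacency)
        )
        for _ in range(30):
            a = random_binary_adjacency(rng, int(rng.integers(3, 10)), 0.5)
            got, _ = local_efficiency(binary_net(a))
            assert got == pytest.approx(brute_local_efficiency(a), abs=1e-12)

    def test_nodal_complete(self, complete4):
        np.testing.assert_allclose(nodal_efficiency(shortest_paths(complete4)).Enod, 1.0)

    def test_nodal_path_end(self, path4):
        enod = nodal_efficiency(shortest_paths(path4)).Enod
        assert enod[0] == pytest.approx(11 / 18)

    def test_isolated_node_zero(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        assert nodal_efficiency(shortest_paths(net)).Enod[3] == 0.0


class TestPhysicalDistance:
    def test_three_four_five_edge(self, node_table4):
        net = net_from_edges(4, [(0, 1)], node_table=node_table4)
        assert physical_distance(net) == pytest.approx(5.0)

    def test_collinear_triangle(self, node_table4):
        # nodes 0,2,3 at z = 0, 2, 4 on the z-axis (node 0 at origin)
        net = net_from_edges(4, [(0, 2), (2, 3), (0, 3)], node_table=node_table4)
        assert physical_distance(net) == pytest.approx(8 / 3)

    def test_duplicate_coordinates_zero(self):
        from netreconfig import NodeTable

        table = NodeTable(
            roi_id=np.arange(3),
            label=np.array(list("abc"), dtype=object),
            coords=np.zeros((3, 3)),
            module=np.array(["M"] * 3, dtype=object),
        )
        net = net_from_edges(3, [(0, 1), (1, 2)], node_table=table)
        assert physical_distance(net) == 0.0

    def test_no_edges_undefined(self, node_table4):
        net = binary_net(np.zeros((4, 4)), node_table=node_table4)
        with pytest.raises(UndefinedMetricError):
            physical_distance(net)


class TestModularity:
    def test_all_in_one_partition_scores_zero(self, rng):
        a = random_binary_adjacency(rng, 8, 0.4)
        if a.sum() == 0:
            a[0, 1] = a[1, 0] = 1
        assert modularity_of_partition(a, [set(range(8))]) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        net = net_from_edges(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])
        q, part = modularity(net, rng=0, n_restarts=20)
        assert q == pytest.approx(0.5)
        assert sorted(map(sorted, part)) == [[0, 1, 2], [3, 4, 5]]

    def test_matches_exhaustive_maximum_on_small_graphs(self, rng):
        checked = 0
        while checked < 20:
            n = int(rng.integers(4, 9))
            a = random_binary_adjacency(rng, n, rng.uniform(0.25, 0.7))
            if np.triu(a, 1).sum() < 1:
                continue
            q, _ = modularity(binary_net(a), rng=checked, n_restarts=100)
            assert q == pytest.approx(exhaustive_max_modularity(a), abs=1e-12)
            checked += 1

    def test_no_edges_rejected(self):
        with pytest.raises(UndefinedMetricError):
            modularity(binary_net(np.zeros((4, 4))))

    def test_never_negative(self, rng):
        for seed in range(10):
            a = random_binary_adjacency(rng, 10, 0.15)
            if np.triu(a, 1).sum() < 1:
                continue
            q, _ = modularity(binary_net(a), rng=seed, n_restarts=5)
            assert q >= 0.0


class TestOracleSuiteAndInvariants:
    def test_all_binary_metrics_match_brute_force(self, rng):
        """Pin every binary metric to the naive implementations on random graphs."""
        for _ in range(200):
            n = int(rng.integers(3, 13))
            a = random_binary_adjacency(rng, n, rng.uniform(0.1, 0.9))
            net = binary_net(a)
            paths = shortest_paths(net)
            np.testing.assert_array_equal(paths.d, floyd_warshall(a))
            assert degree_stats(net)[0] == pytest.approx(a.sum() / n)
            np.testing.assert_allclose(
                clustering(net)[1], brute_clustering(a), atol=1e-12
            )
            assert global_efficiency(paths) == pytest.approx(
                brute_global_efficiency(a), abs=1e-12
            )
            np.testing.assert_allclose(
                nodal_efficiency(paths).Enod, brute_nodal_efficiency(a), atol=1e-12
            )
            if np.isfinite(floyd_warshall(a)[np.triu_indices(n, 1)]).any():
                assert char_path_length(paths) == pytest.approx(
                    brute_char_path_length(a), abs=1e-12
                )

    def test_metric_bounds(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            a = random_binary_adjacency(rng, n, rng.uniform(0.2, 0.8))
            net = binary_net(a)
            cp, _ = clustering(net)
            paths = shortest_paths(net)
            assert 0 <= cp <= 1
            assert 0 <= global_efficiency(paths) <= 1
            assert 0 <= local_efficiency(net)[0] <= 1
            assert np.all((nodal_efficiency(paths).Enod >= 0) & (nodal_efficiency(paths).Enod <= 1))

    def test_adding_edge_monotonicity(self, rng):
        """Adding an edge never decreases Eglob and never increases a finite distance."""
        for _ in range(30):
            n = int(rng.integers(4, 10))
            a = random_binary_adjacency(rng, n, 0.3)
            iu = np.triu_indices(n, 1)
            absent = [(i, j) for i, j in zip(*iu) if a[i, j] == 0]
            if not absent:
                continue
            i, j = absent[int(rng.integers(len(absent)))]
            b = a.copy()
            b[i, j] = b[j, i] = 1
            pa, pb = shortest_paths(binary_net(a)), shortest_paths(binary_net(b))
            assert global_efficiency(pb) >= global_efficiency(pa)
            finite = np.isfinite(pa.d)
            assert np.all(pb.d[finite] <= pa.d[finite])


class TestWeighted:
    def test_unit_weights_reduce_to_binary(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            a = random_binary_adjacency(rng, n, 0.5)
            if np.triu(a, 1).sum() < 1:
                continue
            bnet = binary_net(a)
            wnet = Network(a.copy(), mode="weighted")
            gb, nb = global_metrics(bnet, rng=3, n_restarts=30)
            gw, nw = weighted_metric_suite(wnet, rng=3, n_restarts=30)
            for attr in ("K", "Cp", "Lp", "Eloc", "Eglob", "Q"):
                assert getattr(gw, attr) == pytest.approx(getattr(gb, attr), abs=1e-9)
            np.testing.assert_allclose(nw.Enod, nb.Enod, atol=1e-12)

    def test_two_node_half_weight(self):
        net = net_from_edges(2, [(0, 1)], weights=[0.5])
        k, deg = degree_stats(net)
        assert k == 0.5 and np.all(deg == 0.5)
        paths = shortest_paths(net)
        assert paths.d[0, 1] == pytest.approx(2.0)
        assert global_efficiency(paths) == pytest.approx(0.5)

    def test_equal_weight_triangle_onnela_clustering(self):
        w = 0.37
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)], weights=[w, w, w])
        cp, c = clustering(net)
        # rescaling by the max weight makes every triangle intensity 1
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_weighted_suite_requires_weighted_mode(self, complete4):
        with pytest.raises(ValueError):
            weighted_metric_suite(complete4)
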