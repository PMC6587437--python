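"""Worked examples and oracle equivalence for the five quality metrics."""

import numpy as np
import pytest

from commpat.connectivity import BinaryNetwork
from commpat.detection import Partition
from commpat.metrics import (
    compute_all, distance_based, global_density, local_density, modularity,
    node_membership,
)

from conftest import clique_graph, naive_metrics, random_graph, random_partition


def net_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, 0.5)


def bipartite_2x2():
    """Two size-2 clusters, no internal edges, complete bipartite across."""
    net = net_from_edges(4, [(0, 2), (0, 3), (1, 2), (1, 3)])
    return net, Partition((1, 1, 2, 2))


class TestModularity:
    def test_all_in_one_is_zero(self, rng):
        net = random_graph(rng, 8, 0.5)
        assert modularity(net, Partition((1,) * 8)) == pytest.approx(0.0)

    def test_two_disjoint_edges(self):
        net = net_from_edges(4, [(0, 1), (2, 3)])
        assert modularity(net, Partition((1, 1, 2, 2))) == pytest.approx(0.5)

    def test_bridged_triangles(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        net = net_from_edges(6, edges)
        q = modularity(net, Partition((1, 1, 1, 2, 2, 2)))
        assert q == pytest.approx(5 / 14)

    def test_edgeless_defined_zero(self):
        net = BinaryNetwork(np.zeros((4, 4), dtype=np.int8), 0.5)
        assert modularity(net, Partition((1, 2, 3, 4))) == 0.0


class TestGlobalDensity:
    def test_disjoint_cliques_perfect(self):
        net, part = clique_graph([2, 2])
        assert global_density(net, part) == pytest.approx(1.0)

    def test_antistructure_bipartite(self):
        net, part = bipartite_2x2()
        assert global_density(net, part) == pytest.approx(0.25)

    def test_k3_all_in_one_uses_empty_external_convention(self):
        net, _ = clique_graph([3])
        assert global_density(net, Partition((1, 1, 1))) == pytest.approx(1.0)


class TestLocalDensity:
    def test_disjoint_cliques_perfect(self):
        net, part = clique_graph([3, 3])
        assert local_density(net, part) == pytest.approx(1.0)

    def test_antistructure_bipartite(self):
        net, part = bipartite_2x2()
        assert local_density(net, part) == pytest.approx(0.25)

    def test_edgeless_all_in_one(self):
        net = BinaryNetwork(np.zeros((4, 4), dtype=np.int8), 0.5)
        # q_int = 4/16 from the diagonal convention; q_ext term is empty
        assert local_density(net, Partition((1, 1, 1, 1))) == pytest.approx(0.625)


class TestDistanceBased:
    def test_disjoint_cliques_zero(self):
        net, part = clique_graph([3, 4])
        assert distance_based(net, part) == pytest.approx(0.0)

    def test_complete_k4_split(self):
        net, _ = clique_graph([4])
        assert distance_based(net, Partition((1, 1, 2, 2))) == pytest.approx(0.5)

    def test_edgeless_singletons_zero(self):
        net = BinaryNetwork(np.zeros((2, 2), dtype=np.int8), 0.5)
        assert distance_based(net, Partition((1, 2))) == pytest.approx(0.0)


class TestNodeMembership:
    def test_disjoint_cliques_perfect(self):
        net, part = clique_graph([3, 3])
        assert node_membership(net, part) == pytest.approx(1.0)

    def test_antistructure_bipartite(self):
        net, part = bipartite_2x2()
        assert node_membership(net, part) == pytest.approx(0.25)

    def test_edgeless_two_singletons(self):
        net = BinaryNetwork(np.zeros((2, 2), dtype=np.int8), 0.5)
        assert node_membership(net, Partition((1, 2))) == pytest.approx(1.0)


def test_compute_all_equals_individual_calls(rng):
    net = random_graph(rng, 10, 0.4)
    part = random_partition(rng, 10, 4)
    mv = compute_all(net, part)
    assert mv.as_tuple() == (
        modularity(net, part), global_density(net, part), local_density(net, part),
        distance_based(net, part), node_membership(net, part),
    )


def test_disjoint_clique_fixture_limits():
    net, part = clique_graph([4, 3, 5])
    mv = compute_all(net, part)
    assert mv.q_modularity > 0
    assert mv.q_global_density == pytest.approx(1.0)
    assert mv.q_local_density == pytest.approx(1.0)
    assert mv.q_distance_based == pytest.approx(0.0)
    assert mv.q_node_membership == pytest.approx(1.0)


def test_oracle_equivalence_random_instances(rng):
    """Vectorized metrics match literal formula transcriptions to 1e-12."""
    for _ in range(40):
        n = int(rng.integers(3, 20))
        net = random_graph(rng, n, float(rng.uniform(0.1, 0.9)))
        part = random_partition(rng, n, 6)
        oracle = naive_metrics(net.adjacency, part.as_array())
        mv = compute_all(net, part)
        for got, key in zip(mv.as_tuple(), ("Q", "QGD", "QLD", "QDB", "QNM")):
            assert got == pytest.approx(oracle[key], abs=1e-12), key


def test_density_metrics_in_unit_interval(rng):
    for _ in range(100):
        n = int(rng.integers(2, 15))
        net = random_graph(rng, n, float(rng.uniform(0.0, 1.0)))
        part = random_partition(rng, n, 5)
        mv = compute_all(net, part)
        for v in mv.as_tuple()[1:]:
            assert -1e-12 <= v <= 1 + 1e-12
        assert -0.5 - 1e-12 <= mv.q_modularity <= 1 + 1e-12


def test_node_relabeling_invariance(rng):
    net = random_graph(rng, 12, 0.4)
    part = random_partition(rng, 12, 4)
    perm = rng.permutation(12)
    net_p = BinaryNetwork(net.adjacency[np.ix_(perm, perm)], 0.5)
    part_p = Partition(tuple(int(part.assignment[i]) for i in perm))
    assert np.allclose(compute_all(net, part).as_tuple(),
                       compute_all(net_p, part_p).as_tuple(), atol=1e-12)


def test_dimension_mismatch_rejected(rng):
    net = random_graph(rng, 5, 0.5)
    with pytest.raises(ValueError):
        modularity(net, Partition((1, 1, 2)))
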