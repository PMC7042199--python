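import itertools

import networkx as nx
import numpy as np
import pytest

from connectoml import gmetrics
from connectoml.errors import ConfigurationError, DataError
from conftest import random_binary_graph


def adjacency(edges, n):
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


TWO_TRIANGLES = adjacency([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)


def modularity_edge_loop(A, part):
    """Brute-force oracle: iterate every edge and every module explicitly."""
    n = A.shape[0]
    L = sum(A[i, j] for i in range(n) for j in range(i + 1, n))
    q = 0.0
    for m in set(part):
        nodes = [i for i in range(n) if part[i] == m]
        l_i = sum(A[i, j] for i in nodes for j in nodes if i < j)
        d_i = sum(A[i, j] for i in nodes for j in range(n))
        q += l_i / L - (d_i / (2 * L)) ** 2
    return q


class TestModularityQ:
    def test_single_module_zero(self):
        A = random_binary_graph(10, 0.4, 1)
        P = gmetrics.ModularPartition(tuple([1] * 10))
        assert gmetrics.modularity_q(A, P) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_half(self):
        P = gmetrics.ModularPartition((1, 1, 1, 2, 2, 2))
        assert gmetrics.modularity_q(TWO_TRIANGLES, P) == pytest.approx(0.5)

    def test_matches_edge_loop_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            A = random_binary_graph(12, 0.3, seed + 10)
            if A.sum() == 0:
                continue
            part = tuple(rng.integers(1, 4, size=12))
            part = tuple(np.unique(part, return_inverse=True)[1] + 1)
            P = gmetrics.ModularPartition(part)
            assert gmetrics.modularity_q(A, P) == pytest.approx(
                modularity_edge_loop(A, part), abs=1e-12
            )

    def test_edgeless_error(self):
        with pytest.raises(DataError):
            gmetrics.modularity_q(np.zeros((4, 4), dtype=int), gmetrics.ModularPartition((1, 1, 2, 2)))


def all_partitions(n):
    """Every partition of range(n), as module-id tuples."""
    if n == 1:
        yield (1,)
        return
    for rest in all_partitions(n - 1):
        k = max(rest)
        for m in range(1, k + 2):
            yield rest + (m,)


class TestGreedyModules:
    def test_two_triangles_is_global_optimum(self):
        P = gmetrics.greedy_modules(TWO_TRIANGLES)
        q = gmetrics.modularity_q(TWO_TRIANGLES, P)
        best = max(
            modularity_edge_loop(TWO_TRIANGLES, part) for part in all_partitions(6)
        )
        assert q == pytest.approx(best) == pytest.approx(0.5)
        # partition equals the two triangles
        assert len({P.assignment[i] for i in (0, 1, 2)}) == 1
        assert len({P.assignment[i] for i in (3, 4, 5)}) == 1
        assert P.n_modules == 2

    def test_complete_graph_single_module(self):
        K5 = np.ones((5, 5), dtype=np.int8)
        np.fill_diagonal(K5, 0)
        P = gmetrics.greedy_modules(K5)
        assert P.n_modules == 1
        assert gmetrics.modularity_q(K5, P) == pytest.approx(0.0, abs=1e-12)

    def test_planted_three_blocks_recovered(self):
        rng = np.random.default_rng(4)
        n_per = 8
        blocks = [range(0, 8), range(8, 16), range(16, 24)]
        A = np.zeros((24, 24), dtype=np.int8)
        for block in blocks:
            for i, j in itertools.combinations(block, 2):
                if rng.random() < 0.9:
                    A[i, j] = A[j, i] = 1
        for b1, b2 in itertools.combinations(range(3), 2):
            for i in blocks[b1]:
                for j in blocks[b2]:
                    if rng.random() < 0.05:
                        A[i, j] = A[j, i] = 1
        P = gmetrics.greedy_modules(A)
        truth = np.repeat([1, 2, 3], n_per)
        # same partition up to label permutation
        mapping = {}
        for got, want in zip(P.assignment, truth):
            mapping.setdefault(got, want)
            assert mapping[got] == want

    def test_q_at_least_singleton(self):
        for seed in range(5):
            A = random_binary_graph(15, 0.2, seed + 50)
            if A.sum() == 0:
                continue
            P = gmetrics.greedy_modules(A)
            singleton = gmetrics.ModularPartition(tuple(range(1, 16)))
            assert gmetrics.modularity_q(A, P) >= gmetrics.modularity_q(A, singleton)


class TestModuleDensities:
    def test_triangle_full_density(self):
        P = gmetrics.ModularPartition((1, 1, 1, 2, 2, 2))
        rec = gmetrics.module_densities(TWO_TRIANGLES, P)
        assert rec["intra"][0] == pytest.approx(1.0)
        assert rec["inter"][(1, 2)] == 0.0

    def test_matches_pair_counting(self):
        A = random_binary_graph(10, 0.4, 8)
        part = (1, 1, 1, 2, 2, 2, 3, 3, 3, 3)
        rec = gmetrics.module_densities(A, gmetrics.ModularPartition(part))
        for m in (1, 2, 3):
            nodes = [i for i in range(10) if part[i] == m]
            e = sum(A[i, j] for i, j in itertools.combinations(nodes, 2))
            assert rec["intra"][m - 1] == pytest.approx(
                2 * e / (len(nodes) * (len(nodes) - 1))
            )
        for s, t in itertools.combinations((1, 2, 3), 2):
            ns = [i for i in range(10) if part[i] == s]
            nt = [i for i in range(10) if part[i] == t]
            e = sum(A[i, j] for i in ns for j in nt)
            assert rec["inter"][(s, t)] == pytest.approx(e / (len(ns) * len(nt)))

    def test_singleton_module_flagged(self):
        A = adjacency([(0, 1), (1, 2)], 3)
        rec = gmetrics.module_densities(A, gmetrics.ModularPartition((1, 1, 2)))
        assert rec["undefined_modules"] == [2]
        assert rec["intra"][1] == 0.0


class TestWithinModuleDegree:
    def test_equal_degrees_zero(self):
        P = gmetrics.ModularPartition((1, 1, 1, 2, 2, 2))
        wd = gmetrics.within_module_degree(TWO_TRIANGLES, P)
        np.testing.assert_allclose(wd, 0.0)

    def test_hand_example(self):
        # module of 2 connected nodes with outside-extended degrees {1, 3}
        A = adjacency([(0, 1), (1, 2), (1, 3), (2, 3)], 4)
        P = gmetrics.ModularPartition((1, 1, 1, 2))
        # within module 1: degrees 1 (node0), 3? -> compute by hand instead:
        # node0-1 edge, node1-2 edge, node2 in module1 too
        wd = gmetrics.within_module_degree(A, P)
        e = [1, 2, 1]  # within-module degrees of nodes 0,1,2
        mean, sd = np.mean(e), np.std(e)
        np.testing.assert_allclose(wd[:3], (np.array(e) - mean) / sd)

    def test_zscore_property(self):
        A = random_binary_graph(12, 0.5, 21)
        part = (1,) * 6 + (2,) * 6
        wd = gmetrics.within_module_degree(A, gmetrics.ModularPartition(part))
        for m in (1, 2):
            idx = [i for i in range(12) if part[i] == m]
            sub = wd[idx]
            if np.any(sub != 0):
                assert np.mean(sub) == pytest.approx(0.0, abs=1e-12)
                assert np.std(sub) == pytest.approx(1.0)


class TestParticipationCoefficient:
    def test_all_within_own_module_zero(self):
        P = gmetrics.ModularPartition((1, 1, 1, 2, 2, 2))
        np.testing.assert_allclose(
            gmetrics.participation_coefficient(TWO_TRIANGLES, P), 0.0
        )

    def test_one_edge_per_module(self):
        # node 0 has exactly one edge into each of 3 modules
        A = adjacency([(0, 1), (0, 2), (0, 3)], 4)
        P = gmetrics.ModularPartition((1, 1, 2, 3))
        pc = gmetrics.participation_coefficient(A, P)
        assert pc[0] == pytest.approx(1 - 1 / 3)

    def test_matches_counting_oracle_and_bounds(self):
        A = random_binary_graph(14, 0.4, 33)
        part = tuple(np.random.default_rng(5).integers(1, 4, 14))
        part = tuple(np.unique(part, return_inverse=True)[1] + 1)
        P = gmetrics.ModularPartition(part)
        pc = gmetrics.participation_coefficient(A, P)
        n_mod = P.n_modules
        for i in range(14):
            k = A[i].sum()
            if k == 0:
                assert pc[i] == 0.0
                continue
            acc = sum(
                (sum(A[i, j] for j in range(14) if part[j] == m) / k) ** 2
                for m in range(1, n_mod + 1)
            )
            assert pc[i] == pytest.approx(1 - acc, abs=1e-12)
            assert 0.0 <= pc[i] <= 1 - 1 / n_mod + 1e-12


class TestNodalMetrics:
    def test_triangle_and_path(self):
        tri = adjacency([(0, 1), (1, 2), (0, 2)], 3)
        m = gmetrics.nodal_metrics(tri)
        np.testing.assert_allclose(m["clustering_coefficient"], 1.0)
        p3 = adjacency([(0, 1), (1, 2)], 3)
        m = gmetrics.nodal_metrics(p3)
        assert m["betweenness_centrality"][1] == pytest.approx(1.0)

    def test_star(self):
        star = adjacency([(0, i) for i in range(1, 6)], 6)
        m = gmetrics.nodal_metrics(star)
        assert m["degree_centrality"][0] == 5
        np.testing.assert_allclose(m["degree_centrality"][1:], 1)
        np.testing.assert_allclose(m["clustering_coefficient"], 0.0)

    def test_against_networkx_oracle(self):
        A = random_binary_graph(20, 0.25, 42)
        G = nx.from_numpy_array(A)
        m = gmetrics.nodal_metrics(A)
        bc = nx.betweenness_centrality(G, normalized=False)
        cc = nx.clustering(G)
        for i in range(20):
            assert m["betweenness_centrality"][i] == pytest.approx(bc[i], abs=1e-10)
            assert m["clustering_coefficient"][i] == pytest.approx(cc[i], abs=1e-10)
            assert m["degree_centrality"][i] == G.degree[i]
            lengths = nx.single_source_shortest_path_length(G, i)
            vals = [d for node, d in lengths.items() if node != i]
            expected_spl = np.mean(vals) if vals else 0.0
            assert m["shortest_path_length"][i] == pytest.approx(expected_spl)
            nbrs = list(G.neighbors(i))
            if len(nbrs) >= 2:
                expected_le = nx.global_efficiency(G.subgraph(nbrs))
                assert m["local_efficiency"][i] == pytest.approx(expected_le, abs=1e-10)


class TestGlobalMetrics:
    def test_complete_graph(self):
        K6 = np.ones((6, 6), dtype=np.int8)
        np.fill_diagonal(K6, 0)
        rec = gmetrics.global_metrics(K6, n_random=2, seed=1)
        assert rec["Cp"] == pytest.approx(1.0)
        assert rec["Lp"] == pytest.approx(1.0)
        assert rec["E_global"] == pytest.approx(1.0)

    def test_self_reference_identity(self):
        A = random_binary_graph(15, 0.3, 9)
        rec = gmetrics.global_metrics(A, null_networks=[A])
        assert rec["gamma"] == pytest.approx(1.0)
        assert rec["lambda"] == pytest.approx(1.0)
        assert rec["sigma"] == pytest.approx(1.0)

    def test_ring_lattice_high_gamma(self):
        G = nx.watts_strogatz_graph(50, 4, p=0.0, seed=1)
        A = nx.to_numpy_array(G).astype(np.int8)
        rec = gmetrics.global_metrics(A, n_random=20, seed=3)
        assert rec["gamma"] > 2.0

    def test_rewiring_preserves_degrees(self):
        A = random_binary_graph(30, 0.2, 77)
        rng = np.random.default_rng(0)
        R = gmetrics.rewire_degree_preserving(A, rng)
        np.testing.assert_array_equal(gmetrics.degrees(A), gmetrics.degrees(R))
        assert not np.array_equal(A, R)  # swaps actually happened

    def test_too_small_graph(self):
        with pytest.raises(DataError):
            gmetrics.global_metrics(np.zeros((1, 1), dtype=int), n_random=1)


class TestDetectHubs:
    def test_regular_graph_empty(self):
        ring = adjacency([(i, (i + 1) % 6) for i in range(6)], 6)
        assert gmetrics.detect_hubs(gmetrics.degrees(ring)) == set()

    def test_star_k110_hand_arithmetic(self):
        deg = np.array([10] + [1] * 10)
        mean = 20 / 11
        sd = np.sqrt(np.mean((deg - mean) ** 2))
        assert sd == pytest.approx(2.587, abs=1e-3)
        hubs = gmetrics.detect_hubs(deg)
        assert hubs == {0}
        assert 10 > mean + 2 * sd  # only the center exceeds 6.99

    def test_isolated_node_added(self):
        deg = np.array([10] + [1] * 10)
        hubs_before = gmetrics.detect_hubs(deg)
        deg2 = np.append(deg, 0)
        # brute-force recompute
        thresh = deg2.mean() + 2 * deg2.std()
        expected = {i for i, d in enumerate(deg2) if d > thresh}
        assert gmetrics.detect_hubs(deg2) == expected
        assert hubs_before <= expected


class TestBounds:
    def test_metric_bounds_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for trial in range(50):
            n = int(rng.integers(6, 15))
            A = random_binary_graph(n, float(rng.uniform(0.2, 0.7)), trial)
            if A.sum() == 0:
                continue
            P = gmetrics.greedy_modules(A)
            pc = gmetrics.participation_coefficient(A, P)
            assert np.all(pc >= 0) and np.all(pc <= 1 - 1 / P.n_modules + 1e-12)
            cp = gmetrics.clustering_coefficients(A)
            assert np.all((0 <= cp) & (cp <= 1))
            assert 0 <= gmetrics.global_efficiency(A) <= 1
            dens = gmetrics.module_densities(A, P)
            assert np.all((0 <= dens["intra"]) & (dens["intra"] <= 1))
            for v in dens["inter"].values():
                assert 0 <= v <= 1


class TestSdConventionSwitches:
    def test_wd_sample_sd(self):
        A = random_binary_graph(8, 0.5, 3)
        P = gmetrics.ModularPartition((1,) * 4 + (2,) * 4)
        pop = gmetrics.within_module_degree(A, P)
        samp = gmetrics.within_module_degree(A, P, sample_sd=True)
        for m in (1, 2):
            idx = [i for i in range(8) if P.assignment[i] == m]
            e = A[np.ix_(idx, idx)].sum(axis=1).astype(float)
            if e.std() > 0:
                np.testing.assert_allclose(samp[idx], (e - e.mean()) / e.std(ddof=1))
                assert not np.allclose(pop[idx], samp[idx])

    def test_hub_sample_sd_threshold_higher(self):
        deg = np.array([10] + [1] * 10)
        assert gmetrics.detect_hubs(deg) == {0}
        # sample SD is larger -> threshold higher, hub set can only shrink
        assert gmetrics.detect_hubs(deg, sample_sd=True) <= {0}
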