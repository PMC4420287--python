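import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from activepath.io_formats import PPINetwork
from activepath.subnetwork import (
    CalibrationTable,
    DegenerateCalibrationError,
    DisconnectedModuleError,
    GeneScoreMap,
    SearchParams,
    aggregate_z,
    anneal_search,
    calibrate,
    connected_subsets,
    exhaustive_search,
    find_subnetworks,
    overlap_fraction,
    p_to_z,
    random_connected_set,
    score_subnetwork,
)
from activepath.synthetic import generate_network
from oracles import all_connected_subsets


class TestPToZ:
    def test_median_is_zero(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_against_numeric_cdf_inversion(self):
        # invert the normal CDF numerically as an independent oracle
        p = 0.0227501
        z_oracle = brentq(lambda z: (1 - stats.norm.cdf(z)) - p, -10, 10)
        assert p_to_z(p) == pytest.approx(z_oracle, abs=1e-3)
        assert p_to_z(p) == pytest.approx(2.000, abs=1e-3)

    def test_clamping_keeps_z_finite(self):
        z = p_to_z(1e-300)
        assert math.isfinite(z)
        assert z == pytest.approx(p_to_z(1e-16))

    def test_monotone_decreasing(self):
        ps = np.linspace(0.01, 0.99, 25)
        zs = [p_to_z(p) for p in ps]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_out_of_range_errors(self):
        for bad in (0.0, -0.1, 1.0001):
            with pytest.raises(ValueError):
                p_to_z(bad)


class TestAggregateZ:
    def test_single_identity(self):
        assert aggregate_z([2.0]) == pytest.approx(2.0)

    def test_four_ones(self):
        assert aggregate_z([1, 1, 1, 1]) == pytest.approx(2.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_z([])

    def test_standard_normal_under_null(self):
        # z_i iid N(0,1) => z_A is N(0,1): KS test on 10,000 draws
        rng = np.random.default_rng(12)
        draws = np.array(
            [aggregate_z(rng.normal(size=7)) for _ in range(10_000)]
        )
        assert stats.kstest(draws, "norm").pvalue > 0.01

    def test_monotone_in_member_z(self):
        base = [0.5, -1.0, 2.0]
        higher = [0.9, -1.0, 2.0]
        assert aggregate_z(higher) > aggregate_z(base)


class TestOverlapFraction:
    def test_identical(self):
        assert overlap_fraction({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert overlap_fraction({"a"}, {"b"}) == 0.0

    def test_subset_min_denominator(self):
        small = {f"g{i}" for i in range(5)}
        big = small | {f"h{i}" for i in range(5)}
        assert overlap_fraction(small, big) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            overlap_fraction(set(), {"a"})


class TestGeneScoreMap:
    def test_unscored_genes_get_default_p(self, path_network):
        sm = GeneScoreMap.from_pvalues({"A00": 0.001}, path_network)
        assert sm.p_values["A00"] == 0.001
        assert sm.p_values["A05"] == pytest.approx(0.999)
        assert sm.z("A05") < -3

    def test_genes_not_in_network_dropped(self, path_network, caplog):
        with caplog.at_level("INFO"):
            sm = GeneScoreMap.from_pvalues({"ZZZ": 0.001}, path_network)
        assert "ZZZ" not in sm.p_values
        assert "dropping" in caplog.text


def _uniform_scores(network, seed):
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    return GeneScoreMap.from_pvalues(
        {g: float(p) for g, p in zip(nodes, rng.uniform(1e-6, 1 - 1e-6, len(nodes)))},
        network,
    )


class TestCalibration:
    def test_null_calibrated_scores_standardized(self):
        # uniform p: fresh random size-10 sets standardized by an independent
        # calibration run have mean ~ 0 and sd ~ 1 (tol 0.1)
        network = generate_network(300, seed=5)
        sm = _uniform_scores(network, 5)
        table = calibrate(sm, network, k_range=[10], mc_samples=2000, seed=1)
        adj = {v: list(network.graph[v]) for v in network.graph}
        nodes = sorted(network.nodes)
        rng = np.random.default_rng(99)
        scores = np.array(
            [
                table.standardize(
                    aggregate_z([sm.z(g) for g in random_connected_set(adj, nodes, 10, rng)]),
                    10,
                )
                for _ in range(2000)
            ]
        )
        assert abs(scores.mean()) < 0.1
        assert 0.9 < scores.std(ddof=1) < 1.1

    def test_null_mu_tracks_finite_population_mean(self):
        # with n genes, E[z_A] over random sets is ~ sqrt(k) * mean(z):
        # the calibration table must absorb this finite-pool offset
        network = generate_network(300, seed=5)
        sm = _uniform_scores(network, 5)
        table = calibrate(sm, network, k_range=[10], mc_samples=2000, seed=1)
        z_mean = float(np.mean([sm.z(g) for g in network.nodes]))
        assert table.mu[10] == pytest.approx(math.sqrt(10) * z_mean, abs=0.15)

    def test_k1_exact_enumeration(self, path_network):
        sm = _uniform_scores(path_network, 3)
        table = calibrate(sm, path_network, k_range=[1], mc_samples=100, seed=0)
        z_all = [sm.z(g) for g in sorted(path_network.nodes)]
        assert table.mu[1] == pytest.approx(float(np.mean(z_all)), abs=1e-12)

    def test_constant_z_degenerate(self, path_network):
        sm = GeneScoreMap.from_pvalues(
            {g: 0.25 for g in path_network.nodes}, path_network
        )
        with pytest.raises(DegenerateCalibrationError):
            calibrate(sm, path_network, k_range=[1, 2], mc_samples=100, seed=0)

    def test_deterministic_given_seed(self, path_network):
        sm = _uniform_scores(path_network, 7)
        t1 = calibrate(sm, path_network, k_range=[2, 3], mc_samples=150, seed=9)
        t2 = calibrate(sm, path_network, k_range=[2, 3], mc_samples=150, seed=9)
        assert t1.mu == t2.mu and t1.sigma == t2.sigma

    def test_random_connected_set_is_connected(self, path_network):
        rng = np.random.default_rng(0)
        adj = {v: list(path_network.graph[v]) for v in path_network.graph}
        nodes = sorted(path_network.nodes)
        for _ in range(20):
            genes = random_connected_set(adj, nodes, 6, rng)
            assert nx.is_connected(path_network.graph.subgraph(genes))


class TestScoreSubnetwork:
    @staticmethod
    def _fixed_table():
        return CalibrationTable(mu={1: 0.2, 2: 0.1, 3: 0.0}, sigma={1: 2.0, 2: 1.5, 3: 1.0},
                                mc_samples=100, seed=0)

    def test_centering(self, path_network):
        sm = GeneScoreMap.from_pvalues({"A00": 0.5, "A01": 0.5}, path_network)
        table = CalibrationTable(mu={2: 0.0}, sigma={2: 1.0}, mc_samples=100, seed=0)
        sub = score_subnetwork({"A00", "A01"}, sm, table, path_network)
        # z_A = 0 = mu -> s_A = 0
        assert sub.s_a == pytest.approx(0.0, abs=1e-9)

    def test_scaling(self, path_network):
        sm = _uniform_scores(path_network, 1)
        z_a = aggregate_z([sm.z("A03"), sm.z("A04")])
        table = CalibrationTable(mu={2: z_a - 1.5}, sigma={2: 1.5}, mc_samples=100, seed=0)
        sub = score_subnetwork({"A03", "A04"}, sm, table, path_network)
        assert sub.s_a == pytest.approx(1.0)

    def test_disconnected_errors(self, path_network):
        sm = _uniform_scores(path_network, 1)
        table = CalibrationTable(mu={2: 0.0}, sigma={2: 1.0}, mc_samples=100, seed=0)
        with pytest.raises(DisconnectedModuleError):
            score_subnetwork({"A00", "A10"}, sm, table, path_network)

    def test_planted_module_scores_high(self):
        network = generate_network(200, seed=8)
        nodes = sorted(network.nodes)
        rng = np.random.default_rng(8)
        adj = {v: list(network.graph[v]) for v in network.graph}
        planted = random_connected_set(adj, nodes, 10, rng)
        p_values = {g: (1e-4 if g in planted else float(rng.uniform(0.01, 0.99)))
                    for g in nodes}
        sm = GeneScoreMap.from_pvalues(p_values, network)
        table = calibrate(sm, network, k_range=[10], mc_samples=500, seed=2)
        sub = score_subnetwork(planted, sm, table, network)
        assert sub.s_a > 3


class TestConnectedSubsetEnumeration:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_powerset_oracle(self, seed):
        g = nx.gnm_random_graph(9, 13, seed=seed)
        g = nx.relabel_nodes(g, {v: f"N{v}" for v in g.nodes})
        net = PPINetwork(g)
        ours = set(connected_subsets(net))
        oracle = set(all_connected_subsets(net.graph))
        assert ours == oracle

    def test_path_graph_count(self, path_network):
        # connected subsets of a 20-path are its contiguous intervals: 210
        assert sum(1 for _ in connected_subsets(path_network)) == 20 * 21 // 2


def _calibration_for(network, sm, k_max, seed=0, mc=150):
    return calibrate(sm, network, k_range=range(1, k_max + 1), mc_samples=mc, seed=seed)


class TestAnnealSearch:
    def test_single_strong_gene_on_path(self, path_network):
        p_values = {g: 0.99 for g in path_network.nodes}
        p_values["A07"] = 1e-6
        sm = GeneScoreMap.from_pvalues(p_values, path_network)
        table = _calibration_for(path_network, sm, 8, seed=3)
        params = SearchParams(sa_iterations=2000, restarts=3, seed=5)
        best = anneal_search(path_network, sm, table, params)
        oracle = exhaustive_search(path_network, sm, table)
        assert "A07" in best.genes
        assert best.s_a == pytest.approx(oracle.s_a)

    def test_deterministic_given_seed(self, path_network):
        sm = _uniform_scores(path_network, 4)
        table = _calibration_for(path_network, sm, 8, seed=1)
        params = SearchParams(sa_iterations=1500, restarts=2, seed=11)
        a = anneal_search(path_network, sm, table, params)
        b = anneal_search(path_network, sm, table, params)
        assert a.genes == b.genes
        assert a.s_a == b.s_a

    def test_oracle_equivalence_rate(self):
        # annealing matches brute force on 20-node networks in >= 9/10 runs
        hits = 0
        for seed in range(10):
            g = nx.gnm_random_graph(20, 24, seed=seed)
            g = nx.relabel_nodes(g, {v: f"N{v:02d}" for v in g.nodes})
            if not nx.is_connected(g):
                comps = list(nx.connected_components(g))
                for c in comps[1:]:
                    g.add_edge(next(iter(comps[0])), next(iter(c)))
            net = PPINetwork(g)
            sm = _uniform_scores(net, seed + 100)
            table = _calibration_for(net, sm, 10, seed=seed)
            params = SearchParams(sa_iterations=4000, restarts=5, seed=seed)
            best = anneal_search(net, sm, table, params)
            oracle = exhaustive_search(net, sm, table, k_max=10)
            if best.s_a >= oracle.s_a - 1e-9:
                hits += 1
        assert hits >= 9

    def test_planted_module_recovery(self):
        # 12-gene planted module in a 400-node network: Jaccard >= 0.5 in >= 8/10 seeds
        successes = 0
        for seed in range(10):
            network = generate_network(400, seed=seed)
            nodes = sorted(network.nodes)
            rng = np.random.default_rng(seed + 500)
            adj = {v: list(network.graph[v]) for v in network.graph}
            planted = random_connected_set(adj, nodes, 12, rng)
            p_values = {
                g: (float(rng.uniform(0, 0.001)) or 1e-9) if g in planted
                else float(rng.uniform(1e-6, 1 - 1e-6))
                for g in nodes
            }
            sm = GeneScoreMap.from_pvalues(p_values, network)
            table = _calibration_for(network, sm, 20, seed=seed)
            params = SearchParams(sa_iterations=2500, restarts=5, seed=seed)
            best = anneal_search(network, sm, table, params)
            jacc = len(best.genes & planted) / len(best.genes | planted)
            if jacc >= 0.5:
                successes += 1
        assert successes >= 8


class TestFindSubnetworks:
    def test_single_module(self, path_network):
        sm = _uniform_scores(path_network, 2)
        table = _calibration_for(path_network, sm, 6, seed=0)
        params = SearchParams(n_modules=1, sa_iterations=1000, restarts=2, seed=0)
        modules = find_subnetworks(path_network, sm, table, params)
        assert len(modules) == 1

    def test_overlap_constraint_holds(self):
        network = generate_network(150, seed=3)
        sm = _uniform_scores(network, 3)
        table = _calibration_for(network, sm, 10, seed=3)
        params = SearchParams(n_modules=6, sa_iterations=1200, restarts=2, seed=3)
        modules = find_subnetworks(network, sm, table, params)
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                assert overlap_fraction(a.genes, b.genes) <= 0.5
        # emitted modules are connected and sorted by score
        scores = [m.s_a for m in modules]
        assert scores == sorted(scores, reverse=True)
        for m in modules:
            assert nx.is_connected(network.graph.subgraph(m.genes))

    def test_two_separated_modules_recovered(self):
        # two planted modules on a dumbbell: both recovered as distinct entries
        left = [f"L{i}" for i in range(10)]
        right = [f"R{i}" for i in range(10)]
        edges = list(zip(left, left[1:])) + list(zip(right, right[1:]))
        edges.append((left[-1], right[0]))
        net = PPINetwork.from_edges(edges)
        p_values = {g: 0.9 for g in net.nodes}
        for g in left[:4]:
            p_values[g] = 1e-5
        for g in right[-4:]:
            p_values[g] = 1e-5
        sm = GeneScoreMap.from_pvalues(p_values, net)
        table = _calibration_for(net, sm, 8, seed=4)
        params = SearchParams(n_modules=2, sa_iterations=2500, restarts=4, seed=4,
                              attempts_per_module=4)
        modules = find_subnetworks(net, sm, table, params)
        assert len(modules) == 2
        # each planted region is recovered by exactly one of the two modules
        found_left = any(len(set(left[:4]) & m.genes) >= 3 for m in modules)
        found_right = any(len(set(right[-4:]) & m.genes) >= 3 for m in modules)
        assert found_left and found_right
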