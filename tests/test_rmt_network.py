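import numpy as np
import pytest

from gilnet.expression_io import ExpressionMatrix, ProbeGeneMap
from gilnet import synthetic as syn
from gilnet.rmt_network import (
    GILNetwork,
    SimilarityMatrix,
    build_network,
    collection_summary,
    correlation_matrix,
    find_rmt_threshold,
    network_summary,
    nnsd_chi_square,
    nnsd_critical_value,
    unfold_eigenvalues,
)


def brute_force_pearson(x, y):
    """Two-pass textbook Pearson correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_exact_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = ExpressionMatrix(
            ["s1", "s2", "s3", "s4"], ["x", "y"], np.column_stack([x, -2 * x + 5])
        )
        sim = correlation_matrix(m)
        assert sim.r[0, 0] == 1.0 and sim.r[1, 1] == 1.0
        assert sim.r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        m = ExpressionMatrix(
            ["s1", "s2", "s3"], ["x", "y"],
            np.column_stack([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]),
        )
        sim = correlation_matrix(m)
        assert sim.r[0, 1] == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(2)
        m = ExpressionMatrix(
            [f"s{i}" for i in range(20)],
            [f"p{j}" for j in range(20)],
            rng.normal(size=(20, 20)),
        )
        sim = correlation_matrix(m)
        for i in range(20):
            for j in range(i + 1, 20):
                expect = brute_force_pearson(m.values[:, i], m.values[:, j])
                assert sim.r[i, j] == pytest.approx(expect, abs=1e-12)

    def test_too_few_samples(self):
        m = ExpressionMatrix(["a", "b"], ["p", "q"], np.ones((2, 2)))
        with pytest.raises(ValueError):
            correlation_matrix(m)


class TestNNSD:
    def test_unfolded_spacings_have_unit_mean(self):
        rng = np.random.default_rng(0)
        ev = np.sort(rng.normal(size=500))
        spacings = np.diff(unfold_eigenvalues(ev))
        assert spacings.mean() == pytest.approx(1.0, abs=1e-9)

    def test_exponential_spacings_accepted(self):
        crit = nnsd_critical_value()
        accepted = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            ev = np.cumsum(rng.exponential(1.0, 1500))
            accepted += nnsd_chi_square(ev) <= crit
        assert accepted >= 9

    def test_goe_eigenvalues_rejected(self):
        crit = nnsd_critical_value()
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            A = rng.standard_normal((400, 400))
            ev = np.linalg.eigvalsh((A + A.T) / np.sqrt(2))
            assert nnsd_chi_square(ev) > crit

    def test_too_few_eigenvalues_error(self):
        with pytest.raises(ValueError, match="too_few_genes"):
            nnsd_chi_square(np.arange(10.0))


def planted_similarity(seed=0, n_blocks=8, block=25, n_samples=25, n_noise=300):
    # noise genes supply the random background whose disappearance the
    # scan detects; without them the matrix is modular from the start
    m, truth = syn.generate_compendium(
        n_groups=1, samples_per_group=n_samples, n_genes=n_blocks * block + n_noise,
        modules_per_group=n_blocks, module_size=block, rho=0.95,
        seed=seed, shared_modules=0,
    )
    return correlation_matrix(m), truth


class TestThresholdScan:
    def test_identity_like_matrix_fails(self):
        n = 150
        r = np.eye(n) + 0.01
        np.fill_diagonal(r, 1.0)
        sim = SimilarityMatrix([f"g{i}" for i in range(n)], r, 40)
        scan = find_rmt_threshold(sim)
        assert not scan.success
        assert scan.failure == "no_threshold_found"

    def test_planted_blocks_found_between_start_and_rho(self):
        sim, truth = planted_similarity()
        scan = find_rmt_threshold(sim)
        assert scan.success
        assert 0.5 < scan.threshold < 0.95
        net = build_network(sim, scan.threshold, None, "G0001")
        planted = truth.planted_pairs()
        recall = len(net.edge_set & planted) / len(planted)
        assert recall >= 0.9

    def test_pure_noise_matrix_fails(self):
        rng = np.random.default_rng(8)
        m = ExpressionMatrix(
            [f"s{i}" for i in range(40)],
            [f"g{j}" for j in range(500)],
            rng.normal(size=(40, 500)),
        )
        scan = find_rmt_threshold(correlation_matrix(m))
        assert not scan.success

    def test_restart_above_chosen_returns_higher_threshold(self):
        sim, _ = planted_similarity(seed=4)
        scan = find_rmt_threshold(sim)
        assert scan.success
        rescan = find_rmt_threshold(sim, t_start=round(scan.threshold + 0.02, 3))
        assert (not rescan.success) or rescan.threshold >= scan.threshold


class TestBuildNetwork:
    def test_threshold_above_all_gives_empty_network(self):
        r = np.full((3, 3), 0.4)
        np.fill_diagonal(r, 1.0)
        sim = SimilarityMatrix(["a", "b", "c"], r, 10)
        with pytest.warns(UserWarning, match="no edge"):
            net = build_network(sim, 0.9, None, "G0001")
        assert net.edges == [] and net.nodes == set()

    def test_triangle(self):
        r = np.full((3, 3), 0.99)
        np.fill_diagonal(r, 1.0)
        sim = SimilarityMatrix(["a", "b", "c"], r, 10)
        net = build_network(sim, 0.95, None, "G0001")
        assert len(net.edges) == 3
        assert net.nodes == {"a", "b", "c"}

    def test_edges_match_full_matrix_scan(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 30))
        sim = correlation_matrix(
            ExpressionMatrix([f"s{i}" for i in range(15)], [f"g{j}" for j in range(30)], X)
        )
        t = 0.5
        net = build_network(sim, t, None, "G0001")
        expected = set()
        for i in range(30):
            for j in range(i + 1, 30):
                if abs(sim.r[i, j]) >= t:
                    expected.add(tuple(sorted((sim.ids[i], sim.ids[j]))))
        assert net.edge_set == expected

    def test_probe_collapse_keeps_highest_mean_intensity(self):
        r = np.full((3, 3), 0.99)
        np.fill_diagonal(r, 1.0)
        sim = SimilarityMatrix(
            ["p1", "p2", "p3"], r, 10, mean_intensity=np.array([5.0, 9.0, 7.0])
        )
        pmap = ProbeGeneMap({"p1": ["gA"], "p2": ["gA"], "p3": ["gB"]})
        net = build_network(sim, 0.9, pmap, "G0001")
        # gA represented by p2 (mean 9.0): one edge gA-gB remains
        assert net.nodes == {"gA", "gB"}
        assert len(net.edges) == 1


class TestSummaries:
    @pytest.mark.parametrize(
        "edges,nodes,avg",
        [(19_338, 2_890, 13.38), (34_398, 1_596, 43.11), (3, 3, 2.00)],
    )
    def test_average_degree_arithmetic(self, edges, nodes, avg):
        assert round(2 * edges / nodes, 2) == avg

    def test_triangle_summary(self):
        net = GILNetwork("G1", [("a", "b", 0.99), ("a", "c", 0.99), ("b", "c", 0.99)], 0.9)
        s = network_summary(net)
        assert (s["nodes"], s["edges"], s["avg_degree"]) == (3, 3, 2.00)

    def test_single_network_all_multiplicity_one(self):
        net = GILNetwork("G1", [("a", "b", 0.99), ("b", "c", 0.95)], 0.9)
        s = collection_summary([net])
        assert s["node_fraction_by_multiplicity"] == {1: 100}
        assert s["edge_fraction_by_multiplicity"] == {1: 100}

    def test_identical_networks_all_multiplicity_two(self):
        net1 = GILNetwork("G1", [("a", "b", 0.99)], 0.9)
        net2 = GILNetwork("G2", [("a", "b", 0.98)], 0.9)
        s = collection_summary([net1, net2])
        assert s["node_fraction_by_multiplicity"] == {2: 100}
        assert s["edges_by_multiplicity"] == {2: 1}
        assert s["total_edges"] == 2
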