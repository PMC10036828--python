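import numpy as np
import pytest

from klsnet import (
    apply_sparsity_threshold,
    auc_over_thresholds,
    compute_global_metrics,
    compute_nodal_metrics,
    random_rewire,
)
from klsnet.graph_metrics import ThresholdedNetwork, default_sparsities, sweep_thresholds

import oracles


def complete_graph(n):
    w = np.ones((n, n)) - np.eye(n)
    return ThresholdedNetwork(weights=w, sparsity=1.0, gamma_threshold=0.0)


def ring(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return ThresholdedNetwork(weights=w, sparsity=1.0, gamma_threshold=0.0)


def random_binary(n, p, seed):
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(iu.size) < p
    w[iu[mask], ju[mask]] = 1.0
    return ThresholdedNetwork(weights=w + w.T, sparsity=p, gamma_threshold=0.0)


def random_weighted(n, p, seed):
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(iu.size) < p
    w[iu[mask], ju[mask]] = rng.uniform(0.1, 1.0, mask.sum())
    return ThresholdedNetwork(weights=w + w.T, sparsity=p, gamma_threshold=0.0)


class TestThresholding:
    def test_half_sparsity_keeps_three_largest_of_k4(self, rng):
        w = np.zeros((4, 4))
        iu, ju = np.triu_indices(4, 1)
        w[iu, ju] = rng.permutation([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        w = w + w.T
        t = apply_sparsity_threshold(w, 0.5)
        kept = np.sort(t.weights[np.triu_indices(4, 1)])[::-1][:3]
        np.testing.assert_allclose(kept, [0.9, 0.8, 0.7])
        assert t.n_edges == 3

    def test_third_sparsity_matches_sort_oracle(self):
        w = np.zeros((4, 4))
        iu, ju = np.triu_indices(4, 1)
        vals = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        w[iu, ju] = vals
        w = w + w.T
        t = apply_sparsity_threshold(w, 1 / 3)
        kept = set(t.weights[np.triu_indices(4, 1)]) - {0.0}
        assert kept == set(sorted(vals, reverse=True)[:2])  # {0.9, 0.8}

    def test_full_sparsity_is_identity(self, rng):
        t = random_weighted(6, 1.0, 3)
        out = apply_sparsity_threshold(t.weights, 1.0)
        np.testing.assert_array_equal(out.weights, t.weights)

    def test_edge_count_formula(self):
        t = apply_sparsity_threshold(random_weighted(20, 1.0, 1).weights, 0.13)
        assert t.n_edges == round(0.13 * 20 * 19 / 2)

    def test_ties_broken_deterministically(self):
        w = np.ones((5, 5)) - np.eye(5)  # all ties
        a = apply_sparsity_threshold(w, 0.3)
        b = apply_sparsity_threshold(w, 0.3)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.n_edges == 3

    def test_zero_edges_rejected(self):
        with pytest.raises(ValueError):
            apply_sparsity_threshold(random_weighted(4, 1.0, 0).weights, 0.01)

    def test_gamma_threshold_is_smallest_kept_weight(self):
        t = apply_sparsity_threshold(random_weighted(8, 1.0, 2).weights, 0.4)
        kept = t.weights[np.triu_indices(8, 1)]
        assert t.gamma_threshold == kept[kept > 0].min()


class TestGlobalMetricsClosedForms:
    def test_complete_graph_k4(self):
        gm = compute_global_metrics(complete_graph(4), n_rand=2, seed=0)
        assert gm.cp == pytest.approx(1.0, abs=1e-9)
        assert gm.lp == pytest.approx(1.0, abs=1e-9)
        assert gm.e_global == pytest.approx(1.0, abs=1e-9)
        # rewiring cannot alter a complete graph -> normalized ratios are 1
        assert gm.lambda_ == pytest.approx(1.0, abs=1e-9)
        assert gm.gamma_ == pytest.approx(1.0, abs=1e-9)
        assert gm.sigma == pytest.approx(1.0, abs=1e-9)

    def test_ring_of_ten_path_length(self):
        # distances from any node: 1,1,2,2,3,3,4,4,5 -> mean 25/9
        gm = compute_global_metrics(ring(10), n_rand=1, seed=0)
        assert gm.lp == pytest.approx(25 / 9, abs=1e-9)
        assert gm.lp == pytest.approx(oracles.path_length_mean(ring(10).weights), abs=1e-9)

    def test_synchronizability_closed_forms(self):
        from klsnet.graph_metrics import synchronizability

        # K4 Laplacian spectrum {0, 4, 4, 4}; star S5 {0, 1, 1, 1, 5};
        # ring6 eigenvalues 2 - 2 cos(2 pi k / 6) -> lambda2/lambdamax = 1/4
        assert synchronizability(complete_graph(4).weights) == pytest.approx(1.0, abs=1e-9)
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        assert synchronizability(star) == pytest.approx(1 / 5, abs=1e-9)
        assert synchronizability(ring(6).weights) == pytest.approx(1 / 4, abs=1e-9)

    def test_sigma_definitional_identity(self):
        gm = compute_global_metrics(random_weighted(12, 0.5, 5), n_rand=5, seed=1)
        assert gm.sigma == pytest.approx(gm.gamma_ / gm.lambda_, abs=1e-9)
        assert gm.lambda_ == pytest.approx(gm.lp / gm.lp_rand, abs=1e-9)
        assert gm.gamma_ == pytest.approx(gm.cp / gm.cp_rand, abs=1e-9)


@pytest.mark.parametrize("fixture_seed", [0, 1, 2, 3])
class TestBruteForceEquivalence:
    """Metrics on <= 10-node fixtures vs naive reference implementations."""

    def _net(self, fixture_seed):
        if fixture_seed % 2:
            return random_binary(8, 0.45, fixture_seed)
        return random_weighted(8, 0.55, fixture_seed)

    def test_path_and_efficiency(self, fixture_seed):
        t = self._net(fixture_seed)
        gm = compute_global_metrics(t, n_rand=1, seed=0)
        assert gm.lp == pytest.approx(oracles.path_length_mean(t.weights), abs=1e-9)
        assert gm.e_global == pytest.approx(oracles.global_efficiency(t.weights), abs=1e-9)
        assert gm.e_local == pytest.approx(oracles.local_efficiency(t.weights), abs=1e-9)

    def test_clustering(self, fixture_seed):
        t = self._net(fixture_seed)
        gm = compute_global_metrics(t, n_rand=1, seed=0)
        assert gm.cp == pytest.approx(oracles.clustering_onnela(t.weights).mean(), abs=1e-9)

    def test_hierarchy(self, fixture_seed):
        t = self._net(fixture_seed)
        gm = compute_global_metrics(t, n_rand=1, seed=0)
        assert gm.hr == pytest.approx(oracles.hierarchy_exponent(t.weights), abs=1e-9)

    def test_nodal_degree_and_betweenness(self, fixture_seed):
        t = self._net(fixture_seed)
        nm = compute_nodal_metrics(t)
        np.testing.assert_allclose(nm.dc, t.weights.sum(axis=1), atol=1e-12)
        np.testing.assert_allclose(nm.bc, oracles.betweenness(t.weights), atol=1e-9)
        assert nm.dc.sum() == pytest.approx(t.weights.sum(), abs=1e-9)


class TestAssortativityAndModularity:
    def test_assortativity_matches_pearson_formula(self):
        t = random_binary(9, 0.4, 7)
        gm = compute_global_metrics(t, n_rand=1, seed=0)
        assert gm.ar == pytest.approx(oracles.assortativity_binary(t.weights), abs=1e-9)

    def test_modularity_on_separable_communities(self):
        # two triangles joined by one bridge: greedy must find the optimum
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            w[i, j] = w[j, i] = 1.0
        t = ThresholdedNetwork(weights=w, sparsity=1.0, gamma_threshold=0.0)
        gm = compute_global_metrics(t, n_rand=1, seed=0)
        assert gm.q == pytest.approx(oracles.best_modularity(w), abs=1e-9)

    def test_star_betweenness_closed_form(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        nm = compute_nodal_metrics(
            ThresholdedNetwork(weights=star, sparsity=1.0, gamma_threshold=0.0)
        )
        assert nm.bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        np.testing.assert_allclose(nm.bc[1:], 0.0)

    def test_path_graph_closed_form(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        nm = compute_nodal_metrics(
            ThresholdedNetwork(weights=w, sparsity=1.0, gamma_threshold=0.0)
        )
        np.testing.assert_allclose(nm.dc, [1, 2, 1])
        np.testing.assert_allclose(nm.bc, [0, 1, 0])


class TestRandomRewire:
    def test_degree_sequence_and_edge_count_preserved(self):
        t = random_weighted(12, 0.4, 9)
        null = random_rewire(t, seed=3)
        deg = lambda w: np.sort((w > 0).sum(axis=1))
        np.testing.assert_array_equal(deg(null.weights), deg(t.weights))
        assert null.n_edges == t.n_edges

    def test_weights_are_permuted_multiset(self):
        t = random_weighted(10, 0.5, 11)
        null = random_rewire(t, seed=5)
        orig = np.sort(t.weights[np.triu_indices(10, 1)])
        new = np.sort(null.weights[np.triu_indices(10, 1)])
        np.testing.assert_allclose(orig, new, atol=1e-12)

    def test_rewiring_destroys_lattice_clustering(self):
        # ring-with-chords lattice: each node linked to 2 neighbours each side
        n = 12
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        t = ThresholdedNetwork(weights=w, sparsity=1.0, gamma_threshold=0.0)
        cp0 = oracles.clustering_onnela(w).mean()
        assert cp0 > 0
        cps = []
        for seed in range(50):
            null = random_rewire(t, seed=seed)
            cps.append(oracles.clustering_onnela(null.weights).mean())
        assert np.mean(cps) < cp0

    def test_unswappable_graph_returned_unchanged(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        t = ThresholdedNetwork(weights=w, sparsity=1.0, gamma_threshold=0.0)
        null = random_rewire(t, seed=0)
        np.testing.assert_array_equal((null.weights > 0), (w > 0))


class TestAUC:
    def test_constant_curve(self):
        s = default_sparsities()
        assert auc_over_thresholds(np.ones_like(s), s) == pytest.approx(1.0)

    def test_linear_curve(self):
        s = default_sparsities()
        v = np.linspace(0, 1, len(s))
        assert auc_over_thresholds(v, s) == pytest.approx(0.5, abs=1e-9)

    def test_matches_trapezoid_oracle(self, rng):
        s = default_sparsities()
        v = rng.uniform(-2, 2, len(s))
        assert auc_over_thresholds(v, s) == pytest.approx(
            oracles.trapezoid_auc(v, s), abs=1e-9
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            auc_over_thresholds([1, 2], [0.1, 0.2, 0.3])


class TestSweepProperties:
    def test_eglobal_monotone_in_sparsity(self, rng):
        w = np.zeros((15, 15))
        iu, ju = np.triu_indices(15, 1)
        w[iu, ju] = rng.uniform(0.05, 1.0, iu.size)
        w = w + w.T
        vals = [
            compute_global_metrics(apply_sparsity_threshold(w, s), n_rand=1, seed=0).e_global
            for s in (0.1, 0.2, 0.3, 0.5, 0.8)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_er_null_normalized_ratios_near_one(self):
        t = random_binary(20, 0.3, 21)
        gm = compute_global_metrics(t, n_rand=50, seed=4)
        assert gm.gamma_ == pytest.approx(1.0, abs=0.25)
        assert gm.lambda_ == pytest.approx(1.0, abs=0.1)

    def test_sweep_shapes_and_default_grid(self):
        s = default_sparsities()
        assert len(s) == 49 and s[0] == 0.02 and s[-1] == 0.50
        t = random_weighted(10, 1.0, 2)
        curves, nodal = sweep_thresholds(
            t.weights, sparsities=[0.2, 0.3, 0.4], n_rand=2, seed=0
        )
        assert set(curves) == {
            "Ar", "Q", "Hr", "Eglobal", "Elocal", "Cp", "Lp", "Sr",
            "lambda", "gamma", "sigma",
        }
        assert all(len(c.values) == 3 for c in curves.values())
        assert nodal["Dc"].shape == (3, 10)
        assert nodal["Bc_auc"].shape == (10,)

    def test_zscore_summaries_available(self):
        t = random_binary(12, 0.5, 3)
        gm = compute_global_metrics(t, n_rand=10, seed=0, null_metrics=("Ar", "Sr"))
        z = gm.zscore("Ar")
        mu, sd = gm.null_stats["Ar"]
        assert z == pytest.approx((gm.ar - mu) / sd)
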