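import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from uagscan import build_model, synth
from uagscan._lg import AA_ORDER
from uagscan.genetic_codes import get_code
from uagscan.phylo_ml import (
    SubstitutionModel,
    conditional_probabilities,
    discrete_gamma,
    estimate_alpha,
    hypothesis_scan,
    tree_loglik,
)
from uagscan.seqio import CodonAlignment, ProteinAlignment, Tree


from oracle_helpers import enumeration_loglik, poisson_p_same


class TestDiscreteGamma:
    def test_single_category_is_unit_rate(self):
        assert discrete_gamma(0.37, 1).tolist() == [1.0]

    def test_huge_alpha_collapses_to_point_mass(self):
        rates = discrete_gamma(1e6, 4)
        assert np.all(np.abs(rates - 1) < 1e-2)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 2.0])
    def test_matches_numerical_quadrature(self, alpha):
        """Category means from direct numerical integration of the Gamma pdf."""
        k = 4
        bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1 / alpha)
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            val, _ = quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                lo,
                np.inf if np.isinf(hi) else hi,
            )
            expected.append(k * val)
        assert np.allclose(discrete_gamma(alpha, k), expected, atol=1e-6)

    def test_mean_one_and_non_decreasing(self):
        rng = np.random.default_rng(4)
        for alpha in rng.uniform(0.05, 20, size=20):
            rates = discrete_gamma(alpha, 4)
            assert abs(rates.mean() - 1) < 1e-10
            assert np.all(np.diff(rates) >= 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma(-1, 4)


class TestSubstitutionModel:
    def test_lg_rate_matrix_invariants(self):
        m = build_model(alpha=1.0)
        Q = m.rate_matrix
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -np.sum(m.frequencies * np.diag(Q)) == pytest.approx(1.0)
        P = m.transition_matrix(0.3)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-9)
        # detailed balance of the reversible model
        assert np.allclose(m.frequencies[:, None] * Q, (m.frequencies[:, None] * Q).T)

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 1.0, 5.0])
    def test_uniform_model_matches_closed_form(self, poisson_model, t):
        P = poisson_model.transition_matrix(t)
        assert np.allclose(np.diag(P), poisson_p_same(t), atol=1e-10)

    def test_empirical_frequencies_concentrate_on_observed(self):
        aln = ProteinAlignment(["a", "b"], ["LLLLK", "LLLKK"])
        m = build_model("empirical_from_alignment", alignment=aln)
        freqs = dict(zip(AA_ORDER, m.frequencies))
        assert freqs["L"] > freqs["K"] > freqs["A"] > 0  # smoothing mass elsewhere

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            build_model(alpha=0.0)


class TestTreeLoglik:
    def test_single_leaf_is_log_frequency(self):
        tree = Tree.from_newick("A;")
        m = build_model()
        aln = ProteinAlignment(["A"], ["LLLL"])
        expected = 4 * math.log(m.frequencies[AA_ORDER.index("L")])
        assert tree_loglik(aln, tree, m) == pytest.approx(expected, abs=1e-10)

    def test_two_leaf_poisson_closed_form(self, poisson_model):
        tree = Tree.from_newick("(A:0.3,B:0.2);")
        aln = ProteinAlignment(["A", "B"], ["L", "L"])
        expected = math.log((1 / 20) * poisson_p_same(0.5))
        assert tree_loglik(aln, tree, poisson_model) == pytest.approx(expected, abs=1e-10)
        assert (1 / 20) * poisson_p_same(0.5) == pytest.approx(0.03056, abs=5e-6)

    def test_four_taxon_matches_enumeration(self, small_tree):
        m = build_model(alpha=0.7)
        aln = ProteinAlignment(["A", "B", "C", "D"], ["LKQ", "LKE", "LRQ", "IKQ"])
        assert tree_loglik(aln, small_tree, m) == pytest.approx(
            enumeration_loglik(aln, small_tree, m), abs=1e-10
        )

    def test_pattern_shuffle_leaves_loglik_unchanged(self, small_tree):
        rng = np.random.default_rng(2)
        m = build_model(alpha=0.9)
        cols = ["".join(rng.choice(list(AA_ORDER), size=4)) for _ in range(40)]
        cols += cols[:10]  # duplicated patterns
        perm = rng.permutation(len(cols))
        def aln_from(col_list):
            return ProteinAlignment(
                ["A", "B", "C", "D"],
                ["".join(c[i] for c in col_list) for i in range(4)],
            )
        lnl = tree_loglik(aln_from(cols), small_tree, m)
        lnl_shuffled = tree_loglik(aln_from([cols[i] for i in perm]), small_tree, m)
        assert lnl_shuffled == pytest.approx(lnl, abs=1e-10)

    def test_all_missing_column_contributes_zero(self, small_tree):
        m = build_model()
        base = ProteinAlignment(["A", "B", "C", "D"], ["LK", "LK", "LR", "IK"])
        padded = ProteinAlignment(["A", "B", "C", "D"], ["LKX", "LK-", "LRX", "IKX"])
        assert tree_loglik(padded, small_tree, m) == pytest.approx(
            tree_loglik(base, small_tree, m), abs=1e-10
        )

    def test_leaf_without_sequence_rejected(self, small_tree):
        aln = ProteinAlignment(["A", "B", "C"], ["L", "L", "L"])
        with pytest.raises(ValueError, match="without sequences"):
            tree_loglik(aln, small_tree, build_model())


class TestEstimateAlpha:
    def test_recovery_from_simulated_data(self):
        """Simulation recovery: alpha=0.5, 2000 sites, 12 taxa, 20 seeds."""
        hits = 0
        for seed in range(1, 21):
            tree = synth.random_tree(12, seed=seed)
            spec = synth.SimSpec(
                tree=tree, model=build_model(alpha=0.5), n_background_sites=2000,
                n_reassigned_sites=0, focal=tree.leaf_names[0],
                true_residue="L", seed=seed,
            )
            aln, _ = synth.simulate_alignment(spec)
            est = estimate_alpha(aln, tree, build_model())
            hits += 0.4 <= est.alpha <= 0.62
        assert hits >= 18  # >= 90% of seeds

    def test_rate_homogeneous_data_flagged_at_bound(self):
        tree = synth.random_tree(8, seed=6)
        spec = synth.SimSpec(
            tree=tree, model=build_model(alpha=1.0, ncat=1), n_background_sites=400,
            n_reassigned_sites=0, focal=tree.leaf_names[0],
            true_residue="L", seed=6,
        )
        aln, _ = synth.simulate_alignment(spec)
        with pytest.warns(UserWarning, match="bound"):
            est = estimate_alpha(aln, tree, build_model())
        assert est.at_bound
        assert est.alpha >= 99.0

    def test_optimizer_matches_grid_search(self):
        tree = synth.random_tree(6, seed=9)
        spec = synth.SimSpec(
            tree=tree, model=build_model(alpha=0.6), n_background_sites=300,
            n_reassigned_sites=0, focal=tree.leaf_names[0],
            true_residue="L", seed=9,
        )
        aln, _ = synth.simulate_alignment(spec)
        base = build_model()
        grid = np.exp(np.linspace(np.log(0.02), np.log(100), 200))
        grid_lnl = [tree_loglik(aln, tree, base.with_alpha(a)) for a in grid]
        best = grid[int(np.argmax(grid_lnl))]
        est = estimate_alpha(aln, tree, base)
        spacing = np.log(100 / 0.02) / 199
        assert abs(np.log(est.alpha) - np.log(best)) <= spacing


class TestConditionalProbabilities:
    def test_equal_logliks_give_uniform(self):
        p = conditional_probabilities({aa: -1000.0 for aa in AA_ORDER})
        assert all(v == pytest.approx(0.05) for v in p.values())

    def test_two_hypothesis_closed_form(self):
        p = conditional_probabilities({"a": 0.0, "b": -math.log(3)})
        assert p["a"] == pytest.approx(0.75)
        assert p["b"] == pytest.approx(0.25)

    def test_sum_to_one_and_order_preserved(self):
        rng = np.random.default_rng(0)
        lnl = {aa: float(v) for aa, v in zip(AA_ORDER, -1e5 + 50 * rng.random(20))}
        p = conditional_probabilities(lnl)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
        order_lnl = sorted(lnl, key=lnl.get)
        order_p = sorted(p, key=p.get)
        assert order_lnl == order_p

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            conditional_probabilities({"a": float("nan"), "b": 0.0})
    def test_extreme_spread_is_numerically_stable(self):
        p = conditional_probabilities({"a": -362314.7, "b": -362848.2})
        assert p["a"] == pytest.approx(1.0)
        assert p["b"] > 0


class TestHypothesisScan:
    def test_zero_uag_sites_degenerate(self, small_tree):
        aln = ProteinAlignment(["A", "B", "C", "D"], ["LK", "LK", "LR", "IK"])
        caln = CodonAlignment(
            alignment=aln,
            codon_map={"A": ["CTG", "AAA"]},
            code=get_code("uag_x"),
        )
        scan = hypothesis_scan(caln, small_tree, "A", alpha=1.0)
        assert len(set(round(v, 9) for v in scan.loglik.values())) == 1
        assert all(v == pytest.approx(0.05) for v in scan.cond_prob.values())
        assert scan.n_sites == 0

    def test_recovers_true_leucine(self, scan_fixture):
        scan = hypothesis_scan(
            scan_fixture["caln"], scan_fixture["tree"], scan_fixture["focal"]
        )
        assert scan.best == "L"
        assert scan.cond_prob["L"] > 0.99

    def test_recovers_true_glutamine(self):
        from conftest import make_scan_fixture

        fx = make_scan_fixture(seed=555, true_residue="Q", code_name="uag_gln")
        scan = hypothesis_scan(fx["caln"], fx["tree"], fx["focal"])
        assert scan.best == "Q"
        assert scan.cond_prob["Q"] > 0.99

    def test_fixed_alpha_is_respected(self, scan_fixture):
        scan = hypothesis_scan(
            scan_fixture["caln"], scan_fixture["tree"], scan_fixture["focal"],
            alpha=0.8,
        )
        assert scan.alpha_used == 0.8
        assert scan.best == "L"
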