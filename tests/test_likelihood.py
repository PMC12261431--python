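import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from branchfit.likelihood import (
    LatentCounts,
    LikelihoodConfig,
    LikelihoodError,
    cohort_log_likelihood,
    estimate_true_counts,
    lifetime_risk,
    seq_log_prob,
    tree_log_prob,
)
from branchfit.laws import lifetime_risk_analytic
from branchfit.rates import FitnessMatrix, ModelParams
from branchfit.trees import Cohort, MutationTree
from conftest import chain_params, chain_tree


def observed_tree(lams, counts, ts, c_tumor, mu=1e-3, **kw):
    params = chain_params(lams, mu=mu, **kw)
    tree = chain_tree(len(lams), counts)
    tree.sampling_time = ts
    tree.c_tumor = c_tumor
    tree.c_seq = sum(counts.values())
    return tree, params


class TestLatentCounts:
    def test_proportional_scaling(self):
        tree, _ = observed_tree([0.2, 0.1], {"v1": 50, "v2": 50}, 30.0, 1e6)
        latent = estimate_true_counts(tree)
        assert latent.sizes == {"v1": 500000, "v2": 500000}
        assert latent.c_tumor == 1e6

    def test_internal_zero_node_stays_zero(self):
        tree, _ = observed_tree([0.2, 0.1], {"v1": 0, "v2": 100}, 30.0, 1e6)
        latent = estimate_true_counts(tree)
        assert latent.sizes["v1"] == 0 and latent.sizes["v2"] == 1e6

    def test_largest_remainder_preserves_total(self):
        tree, _ = observed_tree([0.2, 0.1, 0.1], {"v1": 1, "v2": 1, "v3": 1},
                                30.0, 10)
        latent = estimate_true_counts(tree)
        assert sum(latent.sizes.values()) == 10
        assert sorted(latent.sizes.values()) == [3, 3, 4]

    def test_missing_tumor_size_raises(self):
        tree, _ = observed_tree([0.2], {"v1": 10}, 30.0, 1e6)
        tree.c_tumor = None
        with pytest.raises(LikelihoodError, match="C_tumor"):
            estimate_true_counts(tree)


class TestSeqLogProb:
    def test_full_census_has_probability_one(self):
        latent = LatentCounts(sizes={"a": 100}, c_tumor=100)
        assert seq_log_prob(latent, {"a": 100}, 100) == pytest.approx(0.0)

    def test_small_case_closed_form(self):
        latent = LatentCounts(sizes={"a": 2, "b": 2}, c_tumor=4)
        lp = seq_log_prob(latent, {"a": 1, "b": 1}, 2)
        assert lp == pytest.approx(math.log(2 * 2 / 6))

    def test_probabilities_sum_to_one_over_support(self):
        sizes = {"a": 3, "b": 2}
        latent = LatentCounts(sizes=sizes, c_tumor=5)
        total = 0.0
        for ka in range(0, 3):
            kb = 2 - ka
            if kb <= sizes["b"]:
                total += math.exp(seq_log_prob(latent, {"a": ka, "b": kb}, 2))
        assert total == pytest.approx(1.0)

    def test_observed_exceeding_latent_rejected(self):
        latent = LatentCounts(sizes={"a": 3}, c_tumor=3)
        with pytest.raises(LikelihoodError, match="exceeds"):
            seq_log_prob(latent, {"a": 4}, 4)


class TestTreeLogProb:
    def test_single_root_child_breakdown_structure(self):
        tree, params = observed_tree([0.3], {"v1": 100}, 30.0, 1e7)
        bd = tree_log_prob(tree, 30.0, params)
        assert set(bd.node_terms) == {"v1"}
        assert np.isfinite(bd.total)
        assert bd.total == pytest.approx(
            bd.node_terms["v1"] + bd.sampling_term + bd.seq_term)

    def test_invariant_to_node_order_in_file(self):
        counts = {"v1": 60, "v2": 40}
        tree, params = observed_tree([0.2, 0.3], counts, 35.0, 1e7)
        edges = [(None, "root", []), ("root", "v1", [1]), ("v1", "v2", [2])]
        shuffled = MutationTree.from_edges(
            [edges[0], edges[2], edges[1]], counts,
            sampling_time=35.0, c_tumor=1e7)
        shuffled.c_seq = 100
        a = tree_log_prob(tree, 35.0, params).total
        b = tree_log_prob(shuffled, 35.0, params).total
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_size_internal_node_conditions_grandchild_on_ancestor(self):
        tree, params = observed_tree([0.2, 0.1, 0.3],
                                     {"v1": 80, "v2": 0, "v3": 20}, 35.0, 1e7)
        bd = tree_log_prob(tree, 35.0, params)
        assert "v2" not in bd.node_terms
        assert np.isfinite(bd.node_terms["v3"])

    def test_continuity_in_fitness_entries_near_zero(self):
        tree, params = observed_tree([0.05, 0.05], {"v1": 70, "v2": 30},
                                     40.0, 1e6)
        cohort = Cohort(trees=[tree], n=2)

        def ll(dv):
            F = params.F.values.copy()
            F[0, 1] += dv
            p = params.with_F(FitnessMatrix(F))
            return cohort_log_likelihood(cohort, p, None)

        base = ll(0.0)
        diffs = [abs(ll(h) - base) for h in (1e-3, 1e-4, 1e-5)]
        assert diffs[2] < diffs[1] < diffs[0]
        assert diffs[2] < 1e-2 * abs(base) + 1.0


class TestCohortLogLikelihood:
    def test_single_tree_equals_tree_term_minus_log_zeta(self):
        tree, params = observed_tree([0.3], {"v1": 100}, 30.0, 1e7)
        cohort = Cohort(trees=[tree], n=1)
        t_term = tree_log_prob(tree, 30.0, params).total
        zeta = 0.37
        got = cohort_log_likelihood(cohort, params, zeta)
        assert got == pytest.approx(t_term - math.log(zeta))

    def test_zeta_one_disables_conditioning(self):
        tree, params = observed_tree([0.3], {"v1": 100}, 30.0, 1e7)
        cohort = Cohort(trees=[tree], n=1)
        assert cohort_log_likelihood(cohort, params, 1.0) == pytest.approx(
            cohort_log_likelihood(cohort, params, None))

    def test_conditioning_direction_is_exact(self):
        tree, params = observed_tree([0.3], {"v1": 100}, 30.0, 1e7)
        cohort = Cohort(trees=[tree, tree], n=1)
        l1 = cohort_log_likelihood(cohort, params, 0.5)
        l2 = cohort_log_likelihood(cohort, params, 0.25)
        assert l2 - l1 == pytest.approx(-2 * (math.log(0.25) - math.log(0.5)))

    def test_exchangeable_over_trees(self):
        t1, params = observed_tree([0.3], {"v1": 100}, 30.0, 1e7)
        t2, _ = observed_tree([0.3], {"v1": 100}, 26.0, 5e6)
        a = cohort_log_likelihood(Cohort(trees=[t1, t2], n=1), params, 0.5)
        b = cohort_log_likelihood(Cohort(trees=[t2, t1], n=1), params, 0.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invalid_zeta_rejected(self):
        tree, params = observed_tree([0.3], {"v1": 100}, 30.0, 1e7)
        cohort = Cohort(trees=[tree], n=1)
        with pytest.raises(LikelihoodError):
            cohort_log_likelihood(cohort, params, 0.0)

    def test_marginalized_ts_matches_dense_grid_quadrature(self):
        tree, params = observed_tree([0.3], {"v1": 100}, None, 1e7,
                                     C_sampling=1e8, t_max=60.0)
        tree.sampling_time = None
        cohort = Cohort(trees=[tree], n=1)
        got = cohort_log_likelihood(cohort, params, None)
        # oracle: dense trapezoidal grid over (0, t_max]
        grid = np.linspace(1e-3, params.t_max, 3000)
        logs = np.array([
            tree_log_prob(tree, float(t), params).total for t in grid
        ])
        dens = np.exp(logs - logs.max())
        oracle = math.log(np.trapezoid(dens, grid)) + logs.max()
        assert got == pytest.approx(oracle, rel=1e-4)


class TestLifetimeRisk:
    def test_zero_mutation_rate_gives_zero_risk(self):
        params = chain_params([0.3], mu=0.0, t_max=20.0)
        zeta, se = lifetime_risk(params, n_sim=20, seed=1)
        assert zeta == 0.0

    def test_deterministic_given_seed(self):
        params = chain_params([0.5], mu=1e-3, C0=1e4, C_sampling=1e7, t_max=40.0)
        z1, _ = lifetime_risk(params, n_sim=30, seed=7)
        z2, _ = lifetime_risk(params, n_sim=30, seed=7)
        assert z1 == z2

    def test_strong_selection_saturates_risk(self):
        params = chain_params([0.8], mu=1e-2, C0=1e5, C_sampling=1e6, t_max=200.0)
        zeta, _ = lifetime_risk(params, n_sim=30, seed=3)
        assert zeta == 1.0

    def test_monte_carlo_agrees_with_analytic_fold(self):
        params = chain_params([0.4], mu=1e-3, C0=1e4, C_sampling=1e8, t_max=40.0)
        z_mc, se = lifetime_risk(params, n_sim=300, seed=11)
        z_an = lifetime_risk_analytic(params, max_mutations=1)
        assert abs(z_mc - z_an) < 4 * max(se, 0.01)
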