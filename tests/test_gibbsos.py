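"""Seed regression, outlier sum, conditional weights, Gibbs chain."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mapc_gibbsos.gibbsos import (CandidatePool, SamplingTrace, T_SENTINEL,
                                  conditional_weights,
                                  conditional_weights_bruteforce,
                                  gene_level_scores, gibbs_sample, outlier_sum,
                                  regress, run_gibbsos, score_genes)


class TestRegress:
    @pytest.fixture()
    def toy(self):
        # fixed 6x2 design, K=6, M=2, dof=3
        F = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0],
                      [4.0, 3.0], [5.0, 6.0], [6.0, 5.0]])
        y = np.array([2.1, 1.9, 4.2, 3.8, 6.1, 5.9])
        return y, F

    def test_matches_statsmodels_ols(self, toy):
        y, F = toy
        fit = regress(y, F)
        ref = sm.OLS(y, sm.add_constant(F)).fit()
        assert fit.beta_hat == pytest.approx(ref.params[1:], abs=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.mse == pytest.approx(ref.mse_resid, abs=1e-10)
        assert fit.t_stats == pytest.approx(ref.tvalues[1:], abs=1e-8)
        assert fit.dof == 3

    def test_perfect_fit_reports_sentinel_t(self, toy):
        _, F = toy
        y = F @ np.array([1.0, 2.0]) + 0.5
        fit = regress(y, F)
        assert fit.mse == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.abs(fit.t_stats) == T_SENTINEL)

    def test_orthogonal_target_gives_zero_coefficients(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        F = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 1.0],
                      [-1.0, 1.0], [0.0, -1.0], [0.0, -1.0]])
        assert (y @ F == 0).all() and y.sum() == 0
        fit = regress(y, F)
        assert fit.beta_hat == pytest.approx([0.0, 0.0], abs=1e-12)
        assert fit.t_stats == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            regress(rng.normal(size=4), rng.normal(size=(4, 3)))

    def test_rank_deficient_design_flagged(self, rng):
        col = rng.normal(size=8)
        F = np.column_stack([col, col])        # duplicated seed
        fit = regress(rng.normal(size=8), F)
        assert fit.rank_deficient


class TestOutlierSum:
    def test_hand_computed_toy(self):
        # tau(0.025, 10) ~ 2.228: only |3.0| and |-2.8| pass
        assert outlier_sum([3.0, 1.0, -2.8], alpha=0.05, dof=10) == \
            pytest.approx(5.8)

    def test_boundary_value_included(self):
        tau = stats.t.ppf(0.975, 10)
        assert outlier_sum([tau], alpha=0.05, dof=10) == pytest.approx(tau)

    def test_all_below_threshold_gives_zero(self):
        assert outlier_sum([0.5, -1.0, 2.0], alpha=0.05, dof=10) == 0.0

    def test_empty_list_gives_zero(self):
        assert outlier_sum([], alpha=0.05, dof=5) == 0.0

    def test_sign_invariance_two_sided(self, rng):
        t = rng.normal(scale=3, size=20)
        flips = t * rng.choice([-1, 1], size=20)
        assert outlier_sum(t, 0.05, 8) == pytest.approx(
            outlier_sum(flips, 0.05, 8))

    def test_monotone_when_any_t_grows(self):
        base = [3.0, 1.0, -2.8]
        bigger = [3.5, 1.0, -2.8]
        assert outlier_sum(bigger, 0.05, 10) >= outlier_sum(base, 0.05, 10)

    def test_signed_convention_drops_negatives(self):
        assert outlier_sum([3.0, 1.0, -2.8], 0.05, 10, signed=True) == \
            pytest.approx(3.0)


def toy_pool(rng, n_genes=8, K=9, n_tfs=2):
    X = rng.normal(size=(n_genes, K))
    pool = CandidatePool(tf_indices=np.arange(n_tfs),
                         candidates=[np.array([0, 1, 2]),
                                     np.array([3, 4, 5])])
    return X, pool


class TestConditionalWeights:
    def test_normalized_to_one(self, rng):
        X, pool = toy_pool(rng)
        seeds = np.array([0, 3])
        for j in (0, 1):
            w = conditional_weights(j, seeds, X, pool, alpha=0.05)
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()

    def test_single_candidate_gets_unit_weight(self, rng):
        X = rng.normal(size=(4, 8))
        pool = CandidatePool(tf_indices=np.array([0]),
                             candidates=[np.array([2])])
        w = conditional_weights(0, np.array([2]), X, pool)
        assert w == pytest.approx([1.0])

    def test_fast_path_matches_bruteforce(self, rng):
        """FWL residualization equals the literal per-pair OLS route."""
        for _ in range(5):
            X, pool = toy_pool(rng)
            seeds = np.array([rng.choice(pool.candidates[0]),
                              rng.choice(pool.candidates[1])])
            for j in (0, 1):
                fast = conditional_weights(j, seeds, X, pool, alpha=0.2)
                slow = conditional_weights_bruteforce(j, seeds, X, pool,
                                                      alpha=0.2)
                assert fast == pytest.approx(slow, abs=1e-8)

    def test_true_seeds_dominate_noise_seed(self, rng):
        """Seeds that make other candidates fit perfectly absorb the weight."""
        K = 10
        s, u = rng.normal(size=(2, K))
        t = rng.normal(size=K)                 # TF1's lone candidate
        X = np.vstack([s, u, 3 * s, t])
        pool = CandidatePool(tf_indices=np.array([0, 1]),
                             candidates=[np.array([0, 1, 2]),
                                         np.array([3])])
        w = conditional_weights(0, np.array([0, 3]), X, pool)
        # choosing gene 0 (or 2) as seed gives a perfect fit of the other,
        # with sentinel-sized outlier sums; the noise gene 1 yields a tiny OS
        assert w[1] < 1e-3
        assert w[0] + w[2] == pytest.approx(1.0, abs=1e-3)


class TestGibbsSampling:
    def test_frequencies_sum_to_one_per_tf(self, rng):
        X, pool = toy_pool(rng)
        trace = gibbs_sample(X, pool, n_iter=60, burn_in=10, rng=rng)
        for freqs in trace.frequency():
            assert sum(freqs.values()) == pytest.approx(1.0)

    def test_single_tf_marginals_converge_to_weights(self, rng):
        """With one TF the chain is iid sampling from fixed weights."""
        X = rng.normal(size=(6, 12))
        pool = CandidatePool(tf_indices=np.array([0]),
                             candidates=[np.array([0, 1, 2, 3])])
        w = conditional_weights(0, np.array([0]), X, pool, alpha=0.05)
        trace = gibbs_sample(X, pool, n_iter=5000, burn_in=100, rng=7)
        freqs = trace.frequency()[0]
        got = np.array([freqs.get(g, 0.0) for g in pool.candidates[0]])
        assert got == pytest.approx(w, abs=0.02)

    def test_seed_reproducibility(self, rng):
        X, pool = toy_pool(rng)
        a = gibbs_sample(X, pool, n_iter=50, burn_in=10, rng=11)
        b = gibbs_sample(X, pool, n_iter=50, burn_in=10, rng=11)
        assert np.array_equal(a.seeds, b.seeds)

    def test_burn_in_must_be_smaller(self, rng):
        X, pool = toy_pool(rng)
        with pytest.raises(ValueError):
            gibbs_sample(X, pool, n_iter=10, burn_in=10)

    def test_noise_free_recovery_separates_classes(self, rng):
        """All true targets outrank all decoys on clean data (AUC = 1)."""
        K = 12
        S = rng.normal(size=(2, K))
        A = rng.uniform(0.5, 1.5, size=(6, 2))
        fg = A @ S
        bg = rng.normal(size=(4, K)) * fg.std()
        X = np.vstack([fg, bg])
        # every gene is a candidate of both TFs (decoys are false positives)
        W = pd.DataFrame(np.ones((10, 2), dtype=int))
        table = run_gibbsos(X, W, n_iter=300, burn_in=50, rng=3)
        scores = gene_level_scores(table, np.arange(10))
        assert scores[:6].min() > scores[6:].max()

    def test_batching_covers_every_tf(self, rng):
        # K=6 samples cap the design at 4 TFs; 9 TFs need 3 chains
        X = rng.normal(size=(12, 6))
        W = pd.DataFrame(rng.integers(0, 2, size=(12, 9)) | 1)
        table = run_gibbsos(X, W, n_iter=30, burn_in=5, rng=0)
        assert set(table.tf.unique()) == set(range(9))


class TestScores:
    def test_toy_trace_counts(self):
        pool = CandidatePool(tf_indices=np.array([4]),
                             candidates=[np.array([1, 2])])
        trace = SamplingTrace(pool=pool,
                              seeds=np.array([[1], [1], [2], [1]]),
                              burn_in=0, n_iter=4)
        table = score_genes(trace)
        by_gene = table.set_index("gene").frequency
        assert by_gene[1] == pytest.approx(0.75)
        assert by_gene[2] == pytest.approx(0.25)
        assert (table.tf == 4).all()

    def test_absent_gene_scores_zero(self):
        table = pd.DataFrame({"tf": [0], "gene": [1], "frequency": [1.0]})
        scores = gene_level_scores(table, np.array([0, 1, 2]))
        assert scores == pytest.approx([0.0, 1.0, 0.0])
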