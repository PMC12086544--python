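import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from combatmet.betareg import (
    BetaRegression,
    beta_loglik,
    fit_all,
    fit_feature,
    fit_matrix,
)
from combatmet.data import SampleDesign
from oracles import grid_search_loglik


class TestLoglik:
    def test_uniform_case_zero(self):
        # mu=0.5, phi=2 gives Beta(1,1): log-density 0
        assert beta_loglik([0.5], [0.5], [2.0]) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_beta22(self):
        # Beta(2,2) density at 0.5 is 6 * 0.25 = 1.5
        assert beta_loglik([0.5], [0.5], [4.0]) == pytest.approx(np.log(1.5), abs=1e-10)

    def test_variance_convention(self):
        # var = mu(1-mu)/(1+phi): Beta(mu*phi, (1-mu)*phi) at mu=.3, phi=9
        var = stats.beta(0.3 * 9, 0.7 * 9).var()
        assert var == pytest.approx(0.3 * 0.7 / 10.0, abs=1e-12)

    def test_matches_scipy_logpdf(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.05, 0.95, 10)
        mu, phi = 0.4, 7.0
        expected = stats.beta(mu * phi, (1 - mu) * phi).logpdf(y).sum()
        assert beta_loglik(y, np.full(10, mu), np.full(10, phi)) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_loglik([0.0], [0.5], [2.0])
        with pytest.raises(ValueError):
            beta_loglik([0.5], [0.5], [-1.0])


class TestSingleFeatureMLE:
    def test_large_sample_consistency_vs_grid_oracle(self):
        # single batch, no covariate: 2-parameter model, dense grid oracle
        rng = np.random.default_rng(7)
        n = 2000
        design = SampleDesign([f"s{i}" for i in range(n)],
                              np.array(["B1"] * n), np.array(["c"] * n))
        y = np.clip(rng.beta(0.3 * 10, 0.7 * 10, n), 1e-10, 1 - 1e-10)
        fit = fit_feature(y, design)
        assert fit.converged
        assert fit.alpha_hat == pytest.approx(logit(0.3), rel=0.05)
        assert fit.phi_hat[0] == pytest.approx(10.0, rel=0.05)
        # dense 2-D grid over (alpha, log phi)
        alphas = np.linspace(logit(0.3) - 0.3, logit(0.3) + 0.3, 121)
        lphis = np.linspace(np.log(5), np.log(20), 121)
        best = max(
            beta_loglik(y, np.full(n, expit(a)), np.full(n, np.exp(l)))
            for a in alphas for l in lphis
        )
        assert fit.loglik >= best - 1e-4

    def test_logit_shift_recovery(self):
        rng = np.random.default_rng(11)
        n = 4000
        batch = np.array(["B1"] * (n // 2) + ["B2"] * (n // 2))
        cond = np.tile(["c1", "c2"], n // 2)
        design = SampleDesign([f"s{i}" for i in range(n)], batch, cond)
        eta = logit(0.4) + 0.5 * (batch == "B2")
        phi = np.where(batch == "B1", 10.0, 10.0)
        mu = expit(eta)
        y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-10, 1 - 1e-10)
        fit = fit_feature(y, design)
        assert fit.gamma_hat[1] - fit.gamma_hat[0] == pytest.approx(0.5, rel=0.05)

    def test_weighted_gamma_sum_is_zero(self, design_2x2):
        rng = np.random.default_rng(3)
        y = np.clip(rng.beta(2, 2, 20), 1e-6, 1 - 1e-6)
        fit = fit_feature(y, design_2x2)
        n = design_2x2.batch_sizes_array()
        assert abs(n @ fit.gamma_hat) < 1e-8

    def test_reference_mode_zeroes_reference_gamma(self, design_2x2):
        rng = np.random.default_rng(4)
        y = np.clip(rng.beta(2, 5, 20), 1e-6, 1 - 1e-6)
        fit = fit_feature(y, design_2x2, ref_batch="B2")
        assert fit.gamma_hat[design_2x2.batch_levels.index("B2")] == 0.0

    def test_reference_vs_centered_same_fitted_means(self, design_2x2):
        rng = np.random.default_rng(5)
        y = np.clip(rng.beta(2, 5, 20), 1e-6, 1 - 1e-6)
        f1 = fit_feature(y, design_2x2)
        f2 = fit_feature(y, design_2x2, ref_batch="B2")
        np.testing.assert_allclose(f1.mu_hat, f2.mu_hat, atol=1e-6)

    def test_sample_permutation_invariance(self, design_2x2):
        rng = np.random.default_rng(6)
        y = np.clip(rng.beta(2, 2, 20), 1e-6, 1 - 1e-6)
        fit = fit_feature(y, design_2x2)
        perm = rng.permutation(20)
        design_p = SampleDesign(
            [design_2x2.sample_ids[i] for i in perm],
            design_2x2.batch[perm], design_2x2.condition[perm],
        )
        fit_p = fit_feature(y[perm], design_p)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-6)
        order = [design_p.batch_levels.index(b) for b in design_2x2.batch_levels]
        np.testing.assert_allclose(fit_p.gamma_hat[order], fit.gamma_hat, atol=1e-6)

    def test_missing_value_dropped(self, design_2x2):
        rng = np.random.default_rng(8)
        y = np.clip(rng.beta(2, 2, 20), 1e-6, 1 - 1e-6)
        y_na = y.copy()
        y_na[3] = np.nan
        fit = fit_feature(y_na, design_2x2)
        assert fit.n_missing == 1
        assert np.isnan(fit.mu_hat[3])
        assert fit.converged

    def test_near_constant_feature_flagged_not_raised(self, design_2x2):
        y = np.full(20, 0.5)
        y[::2] = 0.5 + 1e-9
        fit = fit_feature(y, design_2x2)  # must not raise
        assert not fit.converged

    def test_results_wrapper_summary(self, design_2x2):
        rng = np.random.default_rng(9)
        y = np.clip(rng.beta(2, 2, 20), 1e-6, 1 - 1e-6)
        res = BetaRegression(y, design_2x2).fit()
        assert res.converged
        text = res.summary()
        assert "gamma" in text and "phi" in text


class TestGridOracleEquivalence:
    def test_mle_beats_coarse_lattice_on_random_instances(self, design_2x2):
        """MLE log-likelihood dominates an independent coarse grid search."""
        rng = np.random.default_rng(123)
        n_instances = 50
        for k in range(n_instances):
            mu0 = rng.uniform(0.2, 0.8)
            gam = rng.uniform(-1, 1)
            bet = rng.uniform(-1, 1)
            phi1, phi2 = rng.uniform(2, 50, 2)
            eta = (logit(mu0) + bet * design_2x2.condition_matrix()[:, 0]
                   + gam * (design_2x2.batch_index() == 1))
            phi = np.where(design_2x2.batch_index() == 0, phi1, phi2)
            mu = expit(eta)
            y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-10, 1 - 1e-10)
            fit = fit_feature(y, design_2x2)
            best_grid = grid_search_loglik(y, design_2x2, n_grid=7)
            assert fit.loglik >= best_grid - 1e-4, f"instance {k}"


class TestBatchedFitting:
    def test_njobs_bit_identical(self, small_matrix, design_2x2):
        fits1 = fit_all(small_matrix, design_2x2, n_jobs=1)
        fits4 = fit_all(small_matrix, design_2x2, n_jobs=4)
        for a, b in zip(fits1, fits4):
            assert a.loglik == b.loglik
            np.testing.assert_array_equal(a.gamma_hat, b.gamma_hat)
            np.testing.assert_array_equal(a.phi_hat, b.phi_hat)

    def test_batched_matches_per_feature(self, small_matrix, design_2x2):
        batched = fit_matrix(small_matrix, design_2x2)
        singles = [fit_feature(small_matrix.values[f], design_2x2)
                   for f in range(5)]
        for f, single in enumerate(singles):
            assert batched.loglik[f] == pytest.approx(single.loglik, abs=1e-9)
            np.testing.assert_allclose(batched.gamma[f], single.gamma_hat, atol=1e-9)

    def test_symmetric_feature(self, design_2x2):
        rng = np.random.default_rng(10)
        y = 0.5 + rng.normal(0, 0.01, size=(1, 20))
        fits = fit_matrix(np.clip(y, 1e-6, 1 - 1e-6), design_2x2)
        assert fits.converged[0]
        assert np.allclose(fits.mu[0], 0.5, atol=0.02)

    def test_sample_id_mismatch_rejected(self, small_matrix):
        other = SampleDesign([f"x{i}" for i in range(20)],
                             np.array(["B1"] * 10 + ["B2"] * 10),
                             np.array(["c1", "c2"] * 10))
        with pytest.raises(ValueError, match="sample IDs"):
            fit_all(small_matrix, other)


class TestRecovery:
    def test_phi_and_gamma_recovery_at_n200_per_batch(self):
        """Median phi error < 10%, median gamma-contrast error < 0.05 logits."""
        rng = np.random.default_rng(2024)
        s = 400
        batch = np.array(["B1"] * 200 + ["B2"] * 200)
        cond = np.tile(["c1", "c2"], 200)
        design = SampleDesign([f"s{i}" for i in range(s)], batch, cond)
        n_feat = 200
        true_gamma_diff = rng.uniform(-1.0, 1.0, n_feat)
        true_phi1 = rng.uniform(5, 40, n_feat)
        true_phi2 = rng.uniform(5, 40, n_feat)
        base = rng.uniform(-1.0, 1.0, n_feat)
        is_b2 = (batch == "B2").astype(float)
        eta = base[:, None] + true_gamma_diff[:, None] * is_b2[None, :]
        phi = np.where(is_b2[None, :] > 0, true_phi2[:, None], true_phi1[:, None])
        mu = expit(eta)
        y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-10, 1 - 1e-10)
        fits = fit_matrix(y, design)
        assert fits.converged.mean() > 0.95
        conv = fits.converged
        rel_err_phi = np.abs(fits.phi[conv] / np.column_stack(
            [true_phi1[conv], true_phi2[conv]]) - 1.0)
        assert np.median(rel_err_phi) < 0.10
        gamma_diff_hat = fits.gamma[conv, 1] - fits.gamma[conv, 0]
        assert np.median(np.abs(gamma_diff_hat - true_gamma_diff[conv])) < 0.05
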