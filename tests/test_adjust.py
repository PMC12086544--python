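import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betainc, expit, logit

from combatmet.adjust import (
    CombatMet,
    batch_free_params,
    combat_met,
    eb_shrink,
    match_quantiles,
)
from combatmet.benchmark import variance_explained
from combatmet.betareg import FeatureFit, fit_matrix
from combatmet.data import BetaValueMatrix, SampleDesign
from combatmet.simulate import SimConfig, make_fig2_instance, simulate_dataset
from oracles import bisect_beta_quantile


def _fit(alpha, gamma, phi, mu, converged=True):
    return FeatureFit(alpha_hat=alpha, beta_hat=np.zeros(0),
                      gamma_hat=np.asarray(gamma, float),
                      phi_hat=np.asarray(phi, float),
                      mu_hat=np.asarray(mu, float), converged=converged,
                      loglik=0.0, n_iter=1)


class TestBatchFreeParams:
    def test_identity_under_no_batch_effect(self, design_2x2):
        mu = np.full(20, 0.4)
        fit = _fit(logit(0.4), [0.0, 0.0], [12.0, 12.0], mu)
        p = batch_free_params(fit, design_2x2)
        np.testing.assert_allclose(p.mu_star, mu)
        assert p.phi_star == pytest.approx(12.0)

    def test_pooled_precision_arithmetic(self, design_2x2):
        # two batches of 10 with phi (10, 20): phi* = (10*10 + 10*20)/20 = 15
        fit = _fit(0.0, [0.1, -0.1], [10.0, 20.0], np.full(20, 0.5))
        assert batch_free_params(fit, design_2x2).phi_star == pytest.approx(15.0)

    def test_logit_shift_removal(self, design_2x2):
        # mu_hat = 0.5 with gamma = log 3 gives mu* = expit(-log 3) = 1/4
        fit = _fit(0.0, [np.log(3.0), -np.log(3.0)], [10.0, 10.0], np.full(20, 0.5))
        p = batch_free_params(fit, design_2x2)
        b1 = design_2x2.batch_index() == 0
        np.testing.assert_allclose(p.mu_star[b1], 0.25, atol=1e-12)

    def test_reference_mode_uses_reference_precision(self, design_2x2):
        fit = _fit(0.0, [0.2, 0.0], [10.0, 20.0], np.full(20, 0.5))
        p = batch_free_params(fit, design_2x2, ref_batch="B2")
        assert p.phi_star == pytest.approx(20.0)

    def test_unknown_reference_rejected(self, design_2x2):
        fit = _fit(0.0, [0.0, 0.0], [10.0, 10.0], np.full(20, 0.5))
        with pytest.raises(ValueError, match="unknown reference"):
            batch_free_params(fit, design_2x2, ref_batch="nope")


class TestMatchQuantiles:
    def test_identity_when_distributions_coincide(self):
        y = np.linspace(0.05, 0.95, 19)
        out = match_quantiles(y, 0.3, 10.0, 0.3, 10.0)
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_symmetric_median_maps_to_median(self):
        assert match_quantiles(0.5, 0.5, 2.0, 0.5, 2.0) == pytest.approx(0.5, abs=1e-12)

    def test_quarter_quantile_against_bisection_oracle(self):
        mu_hat, phi_hat, mu_star, phi_star = 0.3, 10.0, 0.5, 10.0
        y = bisect_beta_quantile(0.25, mu_hat * phi_hat, (1 - mu_hat) * phi_hat)
        out = match_quantiles(y, mu_hat, phi_hat, mu_star, phi_star)
        expected = bisect_beta_quantile(0.25, mu_star * phi_star,
                                        (1 - mu_star) * phi_star)
        assert out == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        y1=st.floats(0.01, 0.99), y2=st.floats(0.01, 0.99),
        mu_hat=st.floats(0.05, 0.95), phi_hat=st.floats(0.5, 80.0),
        mu_star=st.floats(0.05, 0.95), phi_star=st.floats(0.5, 80.0),
    )
    def test_monotone_in_y(self, y1, y2, mu_hat, phi_hat, mu_star, phi_star):
        lo, hi = sorted([y1, y2])
        out_lo = match_quantiles(lo, mu_hat, phi_hat, mu_star, phi_star)
        out_hi = match_quantiles(hi, mu_hat, phi_hat, mu_star, phi_star)
        assert out_lo <= out_hi + 1e-12

    def test_boundary_cells_stay_inside(self):
        out = match_quantiles(np.array([1e-6, 1 - 1e-6]), 0.9, 5.0, 0.1, 50.0)
        assert np.all(out > 0) and np.all(out < 1)


class TestCombatMet:
    def test_single_batch_is_identity(self, single_batch_design):
        rng = np.random.default_rng(0)
        y = np.clip(rng.beta(2, 2, size=(20, 20)), 1e-6, 1 - 1e-6)
        res = combat_met(y, single_batch_design)
        np.testing.assert_allclose(res.adjusted.values, y, atol=1e-8)

    def test_range_preserved_on_adversarial_instance(self):
        matrix, design = make_fig2_instance(seed=0)
        res = CombatMet(matrix, design).fit()
        vals = res.adjusted.values
        assert np.all(vals > 0.0) and np.all(vals < 1.0)

    def test_batch_variance_reduced(self):
        ds = simulate_dataset(SimConfig(batch_mean_diff_pct=10,
                                        batch_precision_fold=5, seed=5,
                                        n_features=200))
        res = CombatMet(ds.beta, ds.design).fit()
        r2_before = variance_explained(ds.beta, ds.design.batch)[1]
        r2_after = variance_explained(res.adjusted, ds.design.batch)[1]
        assert r2_after < r2_before

    def test_covariate_effects_retained(self, design_2x2):
        # condition effect must survive adjustment
        rng = np.random.default_rng(12)
        cond = design_2x2.condition_matrix()[:, 0]
        batch = (design_2x2.batch_index() == 1).astype(float)
        eta = 0.0 + 1.0 * cond + 0.8 * batch
        mu = expit(eta)
        y = np.clip(rng.beta(mu * 50, (1 - mu) * 50, size=(100, 20)),
                    1e-6, 1 - 1e-6)
        res = combat_met(y, design_2x2)
        m_adj = logit(res.adjusted.values)
        diff = m_adj[:, cond == 1].mean() - m_adj[:, cond == 0].mean()
        assert diff == pytest.approx(1.0, abs=0.25)
        b_diff = m_adj[:, batch == 1].mean() - m_adj[:, batch == 0].mean()
        assert abs(b_diff) < 0.1

    def test_passthrough_of_nonconverged_feature(self, design_2x2):
        y = np.vstack([
            np.clip(np.random.default_rng(1).beta(2, 2, 20), 1e-6, 1 - 1e-6),
            np.full(20, 0.5) + np.tile([0, 1e-9], 10),  # near-constant: diverges
        ])
        res = combat_met(y, design_2x2)
        assert res.per_feature_status[1] == "passthrough_nonconverged"
        np.testing.assert_array_equal(res.adjusted.values[1], y[1])

    def test_nan_cells_propagate(self, design_2x2):
        rng = np.random.default_rng(2)
        y = np.clip(rng.beta(2, 2, size=(5, 20)), 1e-6, 1 - 1e-6)
        y[2, 7] = np.nan
        res = combat_met(y, design_2x2)
        assert np.isnan(res.adjusted.values[2, 7])
        assert np.isfinite(res.adjusted.values[2, :7]).all()

    def test_reference_batch_mode_preserves_reference(self, design_2x2):
        ds = simulate_dataset(SimConfig(batch_mean_diff_pct=10,
                                        batch_precision_fold=2, seed=9,
                                        n_features=100))
        res = CombatMet(ds.beta, ds.design, ref_batch="B1").fit()
        ref = ds.design.batch == "B1"
        conv = res.fits.converged
        # reference-batch cells move far less than the adjusted batch's
        delta = np.abs(res.adjusted.values - ds.beta.values)
        assert np.nanmedian(delta[conv][:, ref]) < np.nanmedian(delta[conv][:, ~ref])

    def test_summary_mentions_batches(self, small_matrix, design_2x2):
        res = CombatMet(small_matrix, design_2x2).fit()
        assert "batches: 2" in res.summary()


class TestEBShrink:
    def test_identical_features_unchanged(self, design_2x2):
        rng = np.random.default_rng(3)
        row = np.clip(rng.beta(2, 2, 20), 1e-6, 1 - 1e-6)
        y = np.tile(row, (20, 1))
        fits = fit_matrix(y, design_2x2)
        fits._y = y
        shrunk = eb_shrink(fits, n_mc_features=10, seed=0)
        np.testing.assert_allclose(shrunk.gamma, fits.gamma, atol=1e-10)
        np.testing.assert_allclose(shrunk.phi, fits.phi, atol=1e-8)

    def test_outlier_contracts_toward_bulk(self, design_2x2):
        rng = np.random.default_rng(4)
        batch = (design_2x2.batch_index() == 1).astype(float)
        # 100 homogeneous features with no batch effect, one with a big one
        mu_bulk = expit(rng.normal(0, 0.3, size=(100, 1)) + 0.0 * batch)
        y_bulk = np.clip(rng.beta(mu_bulk * 30, (1 - mu_bulk) * 30, size=(100, 20)),
                         1e-6, 1 - 1e-6)
        mu_out = expit(0.0 + 2.0 * batch)
        y_out = np.clip(rng.beta(mu_out * 30, (1 - mu_out) * 30), 1e-6, 1 - 1e-6)
        y = np.vstack([y_bulk, y_out[None, :]])
        fits = fit_matrix(y, design_2x2)
        fits._y = y
        shrunk = eb_shrink(fits, n_mc_features=50, seed=1)
        bulk_gamma = np.median(fits.gamma[:100, 1])
        raw = abs(fits.gamma[100, 1] - bulk_gamma)
        new = abs(shrunk.gamma[100, 1] - bulk_gamma)
        assert new < raw

    def test_deterministic_given_seed(self, small_matrix, design_2x2):
        fits = fit_matrix(small_matrix, design_2x2)
        fits._y = small_matrix.values
        a = eb_shrink(fits, n_mc_features=10, seed=7)
        b = eb_shrink(fits, n_mc_features=10, seed=7)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_too_few_donors_rejected(self, small_matrix, design_2x2):
        fits = fit_matrix(small_matrix, design_2x2)
        with pytest.raises(ValueError):
            eb_shrink(fits, n_mc_features=1, seed=0)
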