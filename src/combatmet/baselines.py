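"""Gaussian reference methods the benchmark compares against.

``gaussian_combat`` is the classical location/scale empirical-Bayes batch
adjustment (Johnson et al. lineage): per-feature standardization, per-batch
additive (gamma) and multiplicative (delta) batch effects, parametric EB
shrinkage of both across features, then back-transformation.  It is applied
either directly to beta-values (``naive_combat`` — deliberately unclamped,
to expose out-of-range artifacts) or to logit-transformed M-values
(``mvalue_combat``, the standard practice).  ``onestep_design`` builds the
design matrix for modelling batch as a covariate instead of correcting.
"""

from __future__ import annotations

import numpy as np
from scipy.special import polygamma

from .data import BetaValueMatrix, SampleDesign, beta_to_m, m_to_beta

__all__ = ["gaussian_combat", "naive_combat", "mvalue_combat", "onestep_design"]


def _eb_posteriors(z, batch_masks, eb=True, tol=1e-4, max_iter=100):
    """Per-batch location/scale estimates with parametric EB shrinkage.

    z is the standardized F x S data.  Returns gamma_star, delta_star lists
    (one (F,) array per batch).
    """
    gamma_star, delta_star = [], []
    for mask in batch_masks:
        n_i = int(mask.sum())
        zb = z[:, mask]
        g_hat = zb.mean(axis=1)
        if not eb:
            # closed-form mode: exact per-batch location/scale standardization
            gamma_star.append(g_hat)
            delta_star.append(zb.var(axis=1, ddof=0))
            continue
        d_hat = zb.var(axis=1, ddof=1)
        # moment-matched hyperpriors: normal on gamma, inverse-gamma on delta
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1)
        lam = (2.0 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
        g_new = (t2 * n_i * g_hat + d_hat * g_bar) / (t2 * n_i + d_hat)
        d_new = d_hat.copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ss) / (n_i / 2.0 + lam - 1.0)
            g_new = (t2 * n_i * g_hat + d_new * g_bar) / (t2 * n_i + d_new)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-8)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-8)),
            )
            if change < tol:
                break
        gamma_star.append(g_new)
        delta_star.append(d_new)
    return gamma_star, delta_star


def gaussian_combat(data, design, parametric=True, ref_batch=None, eb=True):
    """Classical Gaussian ComBat on an F x S real matrix.

    With ``eb=False`` the adjustment reduces to exact per-batch location and
    scale standardization (useful as a closed-form oracle).  With a
    reference batch, all batches are moved to the reference's location and
    scale and the reference batch's data are returned unchanged.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is provided")
    y = np.asarray(data, dtype=float)
    if y.shape[1] != design.n_samples:
        raise ValueError("data and design sample counts disagree")
    idx = design.batch_index()
    n_b = design.n_batches
    if n_b < 2:
        return y.copy()  # nothing to remove
    batch_masks = [idx == b for b in range(n_b)]
    sizes = design.batch_sizes_array()

    # standardization model: batch cell means + biological covariates
    x = np.column_stack([design.batch_onehot(), design.biological_matrix()])
    beta_hat = np.linalg.lstsq(x, y.T, rcond=None)[0]  # (p, F)
    if ref_batch is None:
        grand = (sizes / sizes.sum()) @ beta_hat[:n_b]  # (F,)
    else:
        ref_batch = str(ref_batch)
        if ref_batch not in design.batch_levels:
            raise ValueError(f"unknown reference batch {ref_batch!r}")
        ref_i = design.batch_levels.index(ref_batch)
        grand = beta_hat[ref_i]
    bio = design.biological_matrix() @ beta_hat[n_b:]  # (S, F)
    stand_mean = grand[None, :] + bio  # (S, F)
    # pooled variance from the full-model residuals (batch means included)
    full_resid = y - (x @ beta_hat).T
    if ref_batch is None:
        var_pooled = (full_resid**2).mean(axis=1)
    else:
        var_pooled = (full_resid[:, batch_masks[ref_i]] ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    z = (y - stand_mean.T) / np.sqrt(var_pooled)[:, None]

    gamma_star, delta_star = _eb_posteriors(z, batch_masks, eb=eb)
    out = np.empty_like(y)
    for b, mask in enumerate(batch_masks):
        g, d = gamma_star[b], np.maximum(delta_star[b], 1e-12)
        out[:, mask] = (z[:, mask] - g[:, None]) / np.sqrt(d)[:, None]
    out = out * np.sqrt(var_pooled)[:, None] + stand_mean.T
    if ref_batch is not None:
        out[:, batch_masks[ref_i]] = y[:, batch_masks[ref_i]]
    return out


def naive_combat(matrix, design, ref_batch=None, eb=True):
    """Gaussian ComBat applied directly to beta-values.

    The output is intentionally not clamped: on skewed data near the
    boundaries the Gaussian model produces adjusted values outside [0, 1],
    which is the failure mode this baseline exists to demonstrate.
    """
    values = matrix.values if isinstance(matrix, BetaValueMatrix) else np.asarray(matrix)
    return gaussian_combat(values, design, ref_batch=ref_batch, eb=eb)


def mvalue_combat(matrix, design, ref_batch=None, eb=True):
    """Gaussian ComBat on logit-transformed M-values; returns beta-values.

    The logit round-trip guarantees outputs strictly inside (0, 1).
    """
    values = matrix.values if isinstance(matrix, BetaValueMatrix) else np.asarray(matrix)
    adjusted_m = gaussian_combat(beta_to_m(values), design, ref_batch=ref_batch, eb=eb)
    adjusted = np.clip(m_to_beta(adjusted_m), 1e-12, 1.0 - 1e-12)
    if isinstance(matrix, BetaValueMatrix):
        return BetaValueMatrix(
            feature_ids=list(matrix.feature_ids),
            sample_ids=list(matrix.sample_ids),
            values=adjusted,
        )
    return adjusted


def onestep_design(design):
    """Design matrix treating batch as a covariate of the differential model.

    Columns: intercept, condition contrasts, numeric covariates, batch
    contrasts (first batch baseline; absent for a single batch).  Raises if
    batch and condition are confounded (rank-deficient).
    """
    x = design.full_design_matrix()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("batch and condition are confounded; one-step design is singular")
    return x


def trigamma_inverse(a):
    """Solve trigamma(x) = a by Newton iteration (for EB variance moderation)."""
    a = np.asarray(a, dtype=float)
    x = 0.5 + 1.0 / a
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / a) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x
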