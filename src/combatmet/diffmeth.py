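"""Per-feature differential methylation testing on M-values.

Each feature's M-values are regressed on intercept + condition (+ optional
extra covariates such as batch indicators for the one-step workflow) and
the condition coefficient is t-tested.  With ``moderation=True`` the
residual variances are shrunk across features by the standard empirical
Bayes inverse-chi-square scheme (hyperparameters ``d0`` and ``s0^2``
moment-matched from the log residual variances), and the moderated t uses
``d_resid + d0`` degrees of freedom — the limma approach.

Scoring against simulation truth uses raw P < alpha (no multiplicity
adjustment), matching the benchmark's definition of TPR and FPR;
Benjamini-Hochberg q-values are available for real-data use.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from .baselines import trigamma_inverse
from .data import BetaValueMatrix, beta_to_m

__all__ = ["mvalue_lm_test", "tpr_fpr", "bh_qvalues"]


def _ols_pvalues(m_vals, x, test_col, moderation):
    f, s = m_vals.shape
    p = x.shape[1]
    df = s - p
    if df <= 0:
        return np.full(f, np.nan), np.full(f, np.nan)
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = m_vals @ (xtx_inv @ x.T).T          # (F, p)
    resid = m_vals - coef @ x.T
    s2 = (resid**2).sum(axis=1) / df
    c = xtx_inv[test_col, test_col]
    if moderation:
        s2_safe = np.maximum(s2, 1e-300)
        z = np.log(s2_safe)
        e = z - digamma(df / 2.0) + np.log(df / 2.0)
        t2 = e.var(ddof=1) - polygamma(1, df / 2.0) if f > 1 else -1.0
        if t2 > 0:
            d0 = 2.0 * float(trigamma_inverse(t2))
            s0_sq = np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0))
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = df + d0
        else:
            # no excess spread in the variances: fully pooled
            s2_post = np.full(f, np.exp(e.mean()))
            df_total = np.inf
    else:
        s2_post = s2
        df_total = df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[:, test_col] / np.sqrt(s2_post * c)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(np.isfinite(t), pvals, np.where(coef[:, test_col] == 0, 1.0, np.nan))
    return pvals, t


def mvalue_lm_test(matrix, design, extra_covariates=None, moderation=True):
    """Per-feature p-values for the condition effect on M-values.

    Parameters
    ----------
    matrix : BetaValueMatrix or (F, S) array of beta-values in (0, 1)
    design : SampleDesign
    extra_covariates : array, optional
        Additional S x K columns (e.g. batch indicators for the one-step
        approach).  Intercept, condition and design covariates are always
        included.
    moderation : bool
        Empirical-Bayes variance moderation (default on).

    Returns
    -------
    numpy.ndarray of per-feature two-sided p-values (NaN where the fit is
    degenerate).
    """
    if isinstance(matrix, BetaValueMatrix):
        m_vals = matrix.m_values()
    else:
        m_vals = beta_to_m(np.asarray(matrix, dtype=float))
    cond = design.condition_matrix()
    if cond.shape[1] == 0:
        raise ValueError("design has a single condition level; nothing to test")
    if cond.shape[1] > 1:
        raise ValueError("testing supports two condition levels")
    blocks = [np.ones((design.n_samples, 1)), cond, design.covariate_matrix()]
    if extra_covariates is not None:
        blocks.append(np.atleast_2d(np.asarray(extra_covariates, dtype=float)))
    x = np.column_stack(blocks)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient test design (confounded covariates?)")

    finite = np.isfinite(m_vals)
    if finite.all():
        pvals, _ = _ols_pvalues(m_vals, x, test_col=1, moderation=moderation)
        return pvals
    pvals = np.full(m_vals.shape[0], np.nan)
    complete = finite.all(axis=1)
    if complete.any():
        pvals[complete], _ = _ols_pvalues(m_vals[complete], x, 1, moderation)
    for fidx in np.where(~complete)[0]:
        w = finite[fidx]
        if w.sum() > x.shape[1]:
            p_f, _ = _ols_pvalues(m_vals[fidx][None, w], x[w], 1, moderation=False)
            pvals[fidx] = p_f[0]
    return pvals


def tpr_fpr(pvals, truth, alpha=0.05):
    """True/false positive rates of a significance call at level ``alpha``.

    ``truth`` is a SimTruth or a boolean is-differential vector.  NaN
    p-values are excluded from numerator and denominator.  With no truly
    differential features the TPR is NaN.
    """
    is_dm = np.asarray(getattr(truth, "is_dm", truth), dtype=bool)
    pvals = np.asarray(pvals, dtype=float)
    if pvals.shape != is_dm.shape:
        raise ValueError("p-value and truth lengths disagree")
    ok = np.isfinite(pvals)
    sig = ok & (pvals < alpha)
    n_dm = int((is_dm & ok).sum())
    n_null = int((~is_dm & ok).sum())
    tpr = float((sig & is_dm).sum() / n_dm) if n_dm else float("nan")
    fpr = float((sig & ~is_dm).sum() / n_null) if n_null else float("nan")
    return tpr, fpr


def bh_qvalues(pvals):
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    pvals = np.asarray(pvals, dtype=float)
    q = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    p = pvals[ok]
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q
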