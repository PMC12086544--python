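"""ComBat-met: quantile-matching batch adjustment of beta-values.

For each feature a beta regression (``combatmet.betareg``) yields fitted
means ``mu_hat_ij``, batch effects ``gamma_hat_i`` and batch precisions
``phi_hat_i``.  The batch-free target distribution for sample ``j`` is

    logit(mu*_j) = logit(mu_hat_ij) - gamma_hat_i,
    phi*         = sum_i n_i phi_hat_i / sum_i n_i,

i.e. the logit batch effect is removed and precision pooled across batches
weighted by batch size.  With a reference batch, ``gamma_hat_i`` is the
offset from the reference and ``phi* = phi_hat_ref``, so every batch is
pulled to the reference's mean and precision and previously adjusted
batches never need revisiting.  Each observation is then mapped to the
value with the same quantile under the batch-free distribution:

    y*_ij = F*^{-1}( F(y_ij; mu_hat_ij, phi_hat_i); mu*_j, phi* ).

Because beta-values are continuous the quantile match is an exact
inverse-CDF evaluation (regularized incomplete beta inverse), which is
monotone and keeps every adjusted value inside (0, 1).  Biological
covariate effects ``X_j beta`` are part of ``mu*_j`` and are preserved.

An optional nonparametric empirical-Bayes shrinkage pools the batch-effect
estimates across features (Monte-Carlo likelihood weighting over a donor
subset).  It is off by default: with a beta likelihood the per-feature
estimates are already robust, and shrinkage under-corrects batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, betaincinv, expit, gammaln, logit

from .betareg import BatchedFits, FeatureFit, fit_matrix
from .data import BetaValueMatrix, SampleDesign

__all__ = [
    "BatchFreeParams",
    "AdjustmentResult",
    "batch_free_params",
    "match_quantiles",
    "eb_shrink",
    "combat_met",
    "CombatMet",
    "CombatMetResults",
]

_Q_CLAMP = 1e-12

STATUS_ADJUSTED = "adjusted"
STATUS_PASSTHROUGH = "passthrough_nonconverged"


@dataclass
class BatchFreeParams:
    """Batch-free beta parameters for one feature: per-sample means and a
    pooled (or reference) precision."""

    mu_star: np.ndarray
    phi_star: float


def _batch_free_arrays(fits: BatchedFits, ref_batch=None, mu=None):
    """Vectorized batch-free parameters for all features.

    ``mu`` optionally overrides the fitted means the batch effect is removed
    from (used when the batch effect comes from shrunk estimates but the
    estimated means are the raw MLE).  Returns mu_star (F, S), phi_star (F,).
    """
    design = fits.design
    idx = design.batch_index()
    if mu is None:
        mu = fits.mu
    gamma_per_sample = fits.gamma[:, idx]              # (F, S)
    eta_star = logit(np.clip(mu, 1e-12, 1 - 1e-12)) - gamma_per_sample
    mu_star = np.clip(expit(eta_star), 1e-12, 1 - 1e-12)
    if ref_batch is None:
        n = design.batch_sizes_array()
        phi_star = (fits.phi @ n) / n.sum()
    else:
        ref_batch = str(ref_batch)
        if ref_batch not in design.batch_levels:
            raise ValueError(f"unknown reference batch {ref_batch!r}")
        phi_star = fits.phi[:, design.batch_levels.index(ref_batch)]
    return mu_star, phi_star


def batch_free_params(fit: FeatureFit, design: SampleDesign, ref_batch=None):
    """Batch-free (mu*_j, phi*) for one fitted feature.

    Removes the per-batch logit offset from each fitted mean and pools the
    batch precisions by sample size (or adopts the reference batch's).
    """
    if not fit.converged:
        raise ValueError("batch-free parameters require a converged fit")
    idx = design.batch_index()
    eta_star = logit(fit.mu_hat) - fit.gamma_hat[idx]
    mu_star = expit(eta_star)
    if ref_batch is None:
        n = design.batch_sizes_array()
        phi_star = float(fit.phi_hat @ n / n.sum())
    else:
        ref_batch = str(ref_batch)
        if ref_batch not in design.batch_levels:
            raise ValueError(f"unknown reference batch {ref_batch!r}")
        phi_star = float(fit.phi_hat[design.batch_levels.index(ref_batch)])
    return BatchFreeParams(mu_star=mu_star, phi_star=phi_star)


def match_quantiles(y, mu_hat, phi_hat, mu_star, phi_star):
    """Map ``y`` through its estimated beta CDF onto the batch-free inverse CDF.

    All arguments broadcast elementwise.  The result is clamped to
    ``[1e-12, 1 - 1e-12]`` so squeezed boundary cells can never be mapped
    onto exactly 0 or 1; the upper tail is inverted through the survival
    function so the map is the exact identity when the two distributions
    coincide.
    """
    y = np.asarray(y, dtype=float)
    a_hat = mu_hat * phi_hat
    b_hat = (1.0 - mu_hat) * phi_hat
    a_star = mu_star * phi_star
    b_star = (1.0 - mu_star) * phi_star
    q = betainc(a_hat, b_hat, y)
    if not np.all(np.isfinite(q) | np.isnan(y)):
        raise FloatingPointError("non-finite CDF value in quantile matching")
    # invert through the survival function in the upper tail, where the
    # forward CDF saturates at 1.0 before betaincinv loses resolution
    qc = betainc(np.asarray(b_hat, dtype=float), a_hat, 1.0 - y)
    lower = np.clip(q, 1e-300, 1.0)
    upper = np.clip(qc, 1e-300, 1.0)
    out = np.where(
        q <= 0.5,
        betaincinv(a_star, b_star, lower),
        1.0 - betaincinv(np.asarray(b_star, dtype=float), a_star, upper),
    )
    return np.clip(out, _Q_CLAMP, 1.0 - _Q_CLAMP)


def eb_shrink(fits, design=None, n_mc_features=500, seed=0):
    """Nonparametric empirical-Bayes shrinkage of batch-effect estimates.

    Pools information across features by Monte-Carlo integration, one batch
    at a time: a feature's ``(gamma_i, phi_i)`` is replaced by a weighted
    average of the estimates of a seeded random donor subset (the feature
    itself excluded), the weight being the beta likelihood of the feature's
    own batch-``i`` data under the donor's ``(gamma_i, phi_i)`` combined
    with the feature's own batch-free mean.  Deterministic given ``seed``.

    Shrinkage attenuates extreme batch-effect estimates toward the pool,
    which typically leaves part of the batch effect in the data (the reason
    it is off by default).

    Accepts and returns either a :class:`BatchedFits` or a list of
    :class:`FeatureFit`.
    """
    as_list = isinstance(fits, (list, tuple))
    if as_list:
        batched = _refits_from_list(fits, design)
    else:
        batched = fits
    design = batched.design
    f_count = batched.n_features
    if n_mc_features < 2:
        raise ValueError("n_mc_features must be >= 2")
    conv = np.where(batched.converged)[0]
    if conv.size < 2:
        raise ValueError("empirical-Bayes shrinkage needs >= 2 converged fits")
    rng = np.random.default_rng(seed)
    n_donor = min(n_mc_features, conv.size)
    donors = rng.choice(conv, size=n_donor, replace=False)

    idx = design.batch_index()
    # biological part of the linear predictor, batch effect removed
    eta_bio = logit(batched.mu) - batched.gamma[:, idx]        # (F, S)
    y = np.clip(_safe(batched), 1e-12, 1 - 1e-12)
    log_y = np.where(batched.mask, np.log(y), 0.0)
    log_1my = np.where(batched.mask, np.log1p(-y), 0.0)

    self_col = np.full(f_count, -1)
    for k, f in enumerate(donors):
        self_col[f] = k
    rows = np.where(self_col >= 0)[0]

    gamma_new = batched.gamma.copy()
    phi_new = batched.phi.copy()
    chunk = max(1, int(2e7 // (n_donor * design.n_samples)))
    for b in range(design.n_batches):
        in_b = idx == b
        g_d = batched.gamma[donors, b]                         # (D,)
        phi_d = batched.phi[donors, b]                         # (D,)
        ll = np.empty((f_count, n_donor))
        for start in range(0, f_count, chunk):
            sl = slice(start, min(start + chunk, f_count))
            mu_fd = np.clip(
                expit(eta_bio[sl][:, None, in_b] + g_d[None, :, None]),
                1e-12, 1 - 1e-12,
            )
            a = mu_fd * phi_d[None, :, None]
            bb = (1.0 - mu_fd) * phi_d[None, :, None]
            terms = (
                gammaln(phi_d[None, :, None])
                - gammaln(a)
                - gammaln(bb)
                + (a - 1.0) * log_y[sl][:, None, in_b]
                + (bb - 1.0) * log_1my[sl][:, None, in_b]
            )
            ll[sl] = np.sum(
                np.where(batched.mask[sl][:, None, in_b], terms, 0.0), axis=2
            )
        w = np.exp(ll - ll.max(axis=1, keepdims=True))
        w[rows, self_col[rows]] = 0.0
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / np.maximum(w_sum, 1e-300), 1.0 / n_donor)
        gamma_new[:, b] = w @ g_d
        phi_new[:, b] = w @ phi_d

    # re-center so the weighted-sum identifiability constraint still holds
    sizes = design.batch_sizes_array()
    shift = gamma_new @ sizes / sizes.sum()
    gamma_new = gamma_new - shift[:, None]
    # keep unconverged features untouched
    keep = ~batched.converged
    gamma_new[keep] = batched.gamma[keep]
    phi_new[keep] = batched.phi[keep]
    mu_new = np.clip(expit(eta_bio + gamma_new[:, idx]), 1e-12, 1 - 1e-12)
    out = BatchedFits(design, batched.alpha.copy(), batched.beta.copy(), gamma_new,
                      phi_new, mu_new, batched.converged.copy(), batched.loglik.copy(),
                      batched.n_iter.copy(), batched.mask.copy())
    out._y = getattr(batched, "_y", None)
    return out.to_feature_fits() if as_list else out


def _safe(batched):
    # observed data attached by combat_met; fall back to fitted means
    y = getattr(batched, "_y", None)
    return y if y is not None else batched.mu


def _refits_from_list(fits, design):
    if design is None:
        raise ValueError("design required when passing a list of FeatureFit")
    alpha = np.array([f.alpha_hat for f in fits])
    beta = np.stack([f.beta_hat for f in fits]) if fits[0].beta_hat.size else np.zeros((len(fits), 0))
    gamma = np.stack([f.gamma_hat for f in fits])
    phi = np.stack([f.phi_hat for f in fits])
    mu = np.stack([np.where(np.isfinite(f.mu_hat), f.mu_hat, 0.5) for f in fits])
    mask = np.stack([np.isfinite(f.mu_hat) for f in fits])
    conv = np.array([f.converged for f in fits])
    ll = np.array([f.loglik for f in fits])
    it = np.array([f.n_iter for f in fits])
    return BatchedFits(design, alpha, beta, gamma, phi, mu, conv, ll, it, mask)


def adjust_from_fits(y, fits, ref_batch=None, batch_params=None):
    """Quantile-match a matrix given already-computed fits.

    ``batch_params``, if given, is a second set of fits whose (gamma, phi)
    define the batch-effect estimates used to build the *batch-free target*
    (this is how empirical-Bayes shrinkage enters: the source distribution
    keeps the raw per-feature MLE, only the removed effect is shrunk).
    Non-converged features pass through unchanged; NaN cells stay NaN.
    Returns (adjusted values, mu_star, phi_star).
    """
    design = fits.design
    target = batch_params if batch_params is not None else fits
    mu_star, phi_star = _batch_free_arrays(
        target, ref_batch=ref_batch, mu=fits.mu
    )
    phi_per_sample = fits.phi[:, design.batch_index()]
    with np.errstate(invalid="ignore"):
        adjusted = match_quantiles(
            np.where(fits.mask, y, np.nan),
            np.clip(fits.mu, 1e-12, 1 - 1e-12),
            phi_per_sample,
            mu_star,
            phi_star[:, None],
        )
    adjusted = np.where(fits.converged[:, None], adjusted, y)
    adjusted = np.where(fits.mask, adjusted, np.nan)
    return adjusted, mu_star, phi_star


@dataclass
class AdjustmentResult:
    """Adjusted matrix plus per-feature status and (optionally) parameters."""

    adjusted: BetaValueMatrix
    per_feature_status: np.ndarray
    fits: BatchedFits | None = None
    mu_star: np.ndarray | None = None
    phi_star: np.ndarray | None = None


def combat_met(matrix, design, ref_batch=None, shrink=False, n_mc_features=500,
               n_jobs=1, seed=0, keep_params=True):
    """Adjust a beta-value matrix for batch effects (functional interface).

    Fits the per-feature beta regressions, optionally shrinks the batch
    parameters across features, computes batch-free distributions and
    quantile-matches every cell.  Non-converged features pass through
    unchanged with a status flag; NaN cells stay NaN.
    """
    model = CombatMet(matrix, design, ref_batch=ref_batch, shrink=shrink,
                      n_mc_features=n_mc_features)
    res = model.fit(n_jobs=n_jobs, seed=seed)
    return AdjustmentResult(
        adjusted=res.adjusted,
        per_feature_status=res.per_feature_status,
        fits=res.fits if keep_params else None,
        mu_star=res.mu_star if keep_params else None,
        phi_star=res.phi_star if keep_params else None,
    )


class CombatMet:
    """Batch-correction model for a beta-value matrix.

    Parameters
    ----------
    matrix : BetaValueMatrix or (F, S) array
        Methylation proportions strictly inside (0, 1) (NaN = missing).
    design : SampleDesign
        Batch, condition and covariate assignment of the samples.
    ref_batch : str, optional
        Adjust every batch to this batch's mean and precision instead of
        the size-weighted cross-batch average.
    shrink : bool
        Apply nonparametric empirical-Bayes shrinkage to the batch-effect
        estimates before adjusting (not recommended; see module docstring).
    n_mc_features : int
        Donor-subset size for the Monte-Carlo shrinkage.
    precision : {"per_batch", "pooled"}
        Precision model of the underlying beta regression.
    """

    def __init__(self, matrix, design, ref_batch=None, shrink=False,
                 n_mc_features=500, precision="per_batch"):
        if isinstance(matrix, np.ndarray):
            matrix = BetaValueMatrix(
                feature_ids=[f"f{i}" for i in range(matrix.shape[0])],
                sample_ids=list(design.sample_ids),
                values=matrix,
            )
        if matrix.sample_ids != design.sample_ids:
            raise ValueError("matrix and design sample IDs disagree")
        self.matrix = matrix
        self.design = design
        self.ref_batch = ref_batch
        self.shrink = shrink
        self.n_mc_features = min(n_mc_features, matrix.shape[0])
        self.mode = {"per_batch": "per_batch_precision",
                     "pooled": "pooled_precision"}[precision]

    def fit(self, n_jobs=1, seed=0, fits=None):
        y = self.matrix.values
        if fits is None:
            fits = fit_matrix(self.matrix, self.design, mode=self.mode,
                              ref_batch=self.ref_batch)
        fits._y = y
        shrunk = None
        if self.shrink:
            shrunk = eb_shrink(fits, n_mc_features=self.n_mc_features, seed=seed)
        adjusted, mu_star, phi_star = adjust_from_fits(
            y, fits, self.ref_batch, batch_params=shrunk
        )
        status = np.where(fits.converged, STATUS_ADJUSTED, STATUS_PASSTHROUGH)
        out = BetaValueMatrix(
            feature_ids=list(self.matrix.feature_ids),
            sample_ids=list(self.matrix.sample_ids),
            values=adjusted,
        )
        return CombatMetResults(self, out, status, fits, mu_star, phi_star)


class CombatMetResults:
    """Fitted batch-correction results: adjusted matrix plus diagnostics."""

    def __init__(self, model, adjusted, status, fits, mu_star, phi_star):
        self.model = model
        self.adjusted = adjusted
        self.per_feature_status = status
        self.fits = fits
        self.mu_star = mu_star
        self.phi_star = phi_star

    @property
    def n_passthrough(self):
        return int((self.per_feature_status == STATUS_PASSTHROUGH).sum())

    def feature_fits(self):
        return self.fits.to_feature_fits()

    def summary(self):
        d = self.model.design
        f, s = self.adjusted.shape
        lines = [
            "ComBat-met batch adjustment",
            f"  features: {f}   samples: {s}   batches: {d.n_batches} "
            f"({', '.join(f'{b}: n={d.batch_sizes[b]}' for b in d.batch_levels)})",
            f"  mode: {'reference batch ' + str(self.model.ref_batch) if self.model.ref_batch else 'cross-batch average'}"
            f"   shrinkage: {'on' if self.model.shrink else 'off'}",
            f"  adjusted features: {f - self.n_passthrough}   "
            f"passed through (non-converged): {self.n_passthrough}",
            f"  median batch precision estimates: "
            + ", ".join(
                f"{b}: {np.median(self.fits.phi[:, k]):.3f}"
                for k, b in enumerate(d.batch_levels)
            ),
        ]
        return "\n".join(lines)
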