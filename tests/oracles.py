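"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: lattice searches,
bisection inversion and direct pmf summation.
"""

import numpy as np
from scipy.special import betainc, expit, gammaln, logit

from combatmet.betareg import beta_loglik


def grid_search_loglik(y, design, n_grid=9):
    """Coarse lattice search over all beta-regression parameters.

    Mean coefficients range over data-driven logit bounds, log-precisions
    over a broad fixed range; returns the best lattice log-likelihood.
    """
    lo, hi = logit(min(y)) - 0.5, logit(max(y)) + 0.5
    alphas = np.linspace(lo, hi, n_grid)
    betas = np.linspace(-2, 2, n_grid)
    gammas = np.linspace(-2, 2, n_grid)
    lphis = np.linspace(np.log(0.5), np.log(200), n_grid)
    x_cond = design.condition_matrix()[:, 0]
    b2 = (design.batch_index() == 1).astype(float)
    idx = design.batch_index()
    best = -np.inf
    for a in alphas:
        for b in betas:
            for g in gammas:
                mu = expit(a + b * x_cond + g * b2)
                for l1 in lphis:
                    for l2 in lphis:
                        phi = np.where(idx == 0, np.exp(l1), np.exp(l2))
                        ll = beta_loglik(y, mu, phi)
                        if ll > best:
                            best = ll
    return best


def bisect_beta_quantile(q, a, b, lo=0.0, hi=1.0, iters=80):
    """Invert the regularized incomplete beta function by bisection."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if betainc(a, b, mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bb_pmf(k, n, mu, theta):
    """Beta-binomial pmf by direct evaluation."""
    a, b = mu * theta, (1 - mu) * theta
    return np.exp(
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + a) - gammaln(a) + gammaln(n - k + b) - gammaln(b)
        + gammaln(theta) - gammaln(n + theta)
    )


def rbetabinom(rng, n, mu, rho, size):
    """Sample beta-binomial counts via the latent beta proportion."""
    theta = (1.0 - rho) / rho
    p = rng.beta(mu * theta, (1 - mu) * theta, size=size)
    return rng.binomial(n, p)
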