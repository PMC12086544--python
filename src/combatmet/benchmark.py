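"""Type-I-error / power benchmark over a grid of injected batch effects.

For every scenario (cross-batch mean difference x precision fold) and
replicate, one dataset is simulated and *every* requested method consumes
that same dataset (paired design), so per-scenario medians are directly
comparable across methods.  A feature is called significant at raw
P < 0.05; TPR and FPR are scored against the simulation truth and the
median (and IQR) across replicates is reported per scenario x method.

Replicate seeds derive deterministically from the master seed via
``numpy.random.SeedSequence([master_seed, scenario_index, replicate])``, so
runs are bit-reproducible and independent of parallelism.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd

from .adjust import CombatMet, adjust_from_fits, eb_shrink
from .baselines import mvalue_combat, onestep_design
from .betareg import fit_matrix
from .biseq import adjust_counts, bb_lrt, fit_bb_matrix
from .data import BetaValueMatrix, beta_to_m
from .diffmeth import mvalue_lm_test, tpr_fpr
from .simulate import SimConfig, simulate_dataset

__all__ = ["run_grid", "run_scenario", "variance_explained", "METHODS"]

METHODS = (
    "no_adjust",
    "combat_met",
    "combat_met_shrink",
    "mvalue_combat",
    "onestep",
    "combat_biseq",
)


def replicate_seed(master_seed, scenario_index, replicate):
    """Deterministic per-replicate seed (stable across versions and n_jobs)."""
    ss = np.random.SeedSequence([int(master_seed), int(scenario_index), int(replicate)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _method_pvalues(method, dataset, alpha_moderation=True, n_mc_features=500,
                    shrink_seed=0, _cache=None):
    beta, design, counts = dataset.beta, dataset.design, dataset.counts
    if method == "no_adjust":
        return mvalue_lm_test(beta, design, moderation=alpha_moderation)
    if method == "onestep":
        batch_cols = onestep_design(design)[:, -(design.n_batches - 1):]
        return mvalue_lm_test(beta, design, extra_covariates=batch_cols,
                              moderation=alpha_moderation)
    if method == "mvalue_combat":
        adj = mvalue_combat(beta, design)
        return mvalue_lm_test(adj, design, moderation=alpha_moderation)
    if method in ("combat_met", "combat_met_shrink"):
        if _cache is not None and "beta_fits" in _cache:
            fits = _cache["beta_fits"]
        else:
            fits = fit_matrix(beta, design)
            fits._y = beta.values
            if _cache is not None:
                _cache["beta_fits"] = fits
        shrunk = None
        if method == "combat_met_shrink":
            shrunk = eb_shrink(fits, n_mc_features=min(n_mc_features, beta.shape[0]),
                               seed=shrink_seed)
        adjusted, _, _ = adjust_from_fits(beta.values, fits, batch_params=shrunk)
        return mvalue_lm_test(adjusted, design, moderation=alpha_moderation)
    if method == "combat_biseq":
        fits = fit_bb_matrix(counts, design)
        adj = adjust_counts(counts.methylated, counts.coverage, fits, design)
        return bb_lrt(adj, counts.coverage, design)
    raise ValueError(f"unknown method {method!r}")


def run_scenario(mean_diff, fold, methods, n_reps, seed, scenario_index=0,
                 n_samples=20, alpha=0.05, sim_overrides=None):
    """All replicates of one grid cell; returns per-replicate TPR/FPR arrays.

    ``sim_overrides`` may perturb non-grid simulator settings (e.g. the
    base-proportion mixture) for robustness checks.
    """
    recs = {m: {"tpr": [], "fpr": []} for m in methods}
    n_failed = {m: 0 for m in methods}
    for rep in range(n_reps):
        rep_seed = replicate_seed(seed, scenario_index, rep)
        cfg_kwargs = dict(
            batch_mean_diff_pct=mean_diff,
            batch_precision_fold=fold,
            n_samples=n_samples,
            seed=rep_seed,
        )
        if sim_overrides:
            cfg_kwargs.update(sim_overrides)
        dataset = simulate_dataset(SimConfig(**cfg_kwargs))
        cache = {}
        for m in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pvals = _method_pvalues(m, dataset, shrink_seed=rep_seed,
                                            _cache=cache)
                t, fp = tpr_fpr(pvals, dataset.truth, alpha=alpha)
            except Exception:
                n_failed[m] += 1
                continue
            recs[m]["tpr"].append(t)
            recs[m]["fpr"].append(fp)
    return recs, n_failed


def run_grid(methods=("no_adjust", "combat_met", "mvalue_combat"),
             mean_diffs=(0, 2, 5, 10), folds=(1, 2, 5, 10), n_reps=50,
             n_samples=20, seed=0, n_jobs=1, alpha=0.05, sim_overrides=None):
    """Median TPR/FPR per scenario x method over paired replicates.

    Returns a DataFrame with columns mean_diff_pct, precision_fold, method,
    n_reps, n_failed, median_tpr, median_fpr, iqr_tpr, iqr_fpr, seed.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    scenarios = list(product(mean_diffs, folds))
    rows = []
    for s_idx, (md, fold) in enumerate(scenarios):
        recs, n_failed = run_scenario(md, fold, methods, n_reps, seed,
                                      scenario_index=s_idx, n_samples=n_samples,
                                      alpha=alpha, sim_overrides=sim_overrides)
        for m in methods:
            tpr = np.asarray(recs[m]["tpr"], dtype=float)
            fpr = np.asarray(recs[m]["fpr"], dtype=float)
            q_t = np.nanpercentile(tpr, [25, 50, 75]) if tpr.size else [np.nan] * 3
            q_f = np.nanpercentile(fpr, [25, 50, 75]) if fpr.size else [np.nan] * 3
            rows.append({
                "mean_diff_pct": md,
                "precision_fold": fold,
                "method": m,
                "n_reps": len(recs[m]["tpr"]),
                "n_failed": n_failed[m],
                "median_tpr": q_t[1],
                "median_fpr": q_f[1],
                "iqr_tpr": q_t[2] - q_t[0],
                "iqr_fpr": q_f[2] - q_f[0],
                "seed": seed,
            })
    return pd.DataFrame(rows)


def variance_explained(matrix, batch):
    """Per-feature fraction of variance explained by batch, and its mean.

    A one-way between/total sum-of-squares decomposition on M-values (the
    matrix is logit-transformed if it is a beta-value container; real-valued
    input is used as is).  Constant features score 0 by convention.

    Returns (r2 array, mean r2).
    """
    if isinstance(matrix, BetaValueMatrix):
        y = matrix.m_values()
    else:
        y = np.asarray(matrix, dtype=float)
        if np.nanmin(y) > 0.0 and np.nanmax(y) < 1.0:
            y = beta_to_m(y)
    batch = np.asarray(batch)
    levels = pd.unique(batch)
    if len(levels) < 2:
        raise ValueError("variance decomposition needs >= 2 batches")
    grand = np.nanmean(y, axis=1, keepdims=True)
    sst = np.nansum((y - grand) ** 2, axis=1)
    ssb = np.zeros_like(sst)
    for lev in levels:
        mask = batch == lev
        mb = np.nanmean(y[:, mask], axis=1)
        ssb += np.sum(np.isfinite(y[:, mask]), axis=1) * (mb - grand[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssb / np.maximum(sst, 1e-300), 0.0)
    return r2, float(np.mean(r2))
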