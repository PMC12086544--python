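"""Synthetic bisulfite-sequencing data with injected batch effects.

The generator emulates a methylKit-dataSim-style study: a balanced two
condition x two batch design, per-feature base methylation proportions
drawn from a bimodal beta mixture (CpG methylation is predominantly low or
high), negative-binomial sequencing coverage, a beta-distributed biological
proportion per cell, and binomial methylated counts given coverage.

Batch effects are injected at the distribution level: batch 2 shifts each
feature's mean proportion by ``batch_mean_diff_pct`` percentage points (sign
alternating per feature by a seeded coin flip, so both directions occur)
and uses precision ``baseline_precision * batch_precision_fold`` while batch
1 stays at the baseline.  Truly differential features add
``effect_pct`` percentage points under condition 2.

Defaults mirror the benchmark study conditions: 1000 features, 20 samples,
100 differential features with a +10 percentage-point effect, baseline
precision 10, mean coverage 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BetaValueMatrix, CountMatrixPair, SampleDesign

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset", "simulate_dataset",
           "make_fig2_instance"]

MEAN_DIFF_GRID = (0, 2, 5, 10)
PRECISION_FOLD_GRID = (1, 2, 5, 10)


@dataclass
class SimConfig:
    """Study conditions of one simulated dataset."""

    n_features: int = 1000
    n_samples: int = 20
    n_dm: int = 100
    effect_pct: float = 10.0
    batch_mean_diff_pct: float = 0.0
    batch_precision_fold: float = 1.0
    baseline_precision: float = 10.0
    mean_coverage: float = 30.0
    coverage_dispersion: float = 5.0
    seed: int = 0
    # base-proportion mixture: low-methylation and high-methylation modes
    mixture_shapes: tuple = ((0.6, 2.4), (2.4, 0.6))

    def __post_init__(self):
        if self.n_dm > self.n_features:
            raise ValueError("n_dm cannot exceed n_features")
        if self.n_samples % 4 != 0:
            raise ValueError("balanced 2x2 design needs n_samples divisible by 4")
        if self.batch_mean_diff_pct not in MEAN_DIFF_GRID:
            raise ValueError(f"batch_mean_diff_pct must be one of {MEAN_DIFF_GRID}")
        if self.batch_precision_fold not in PRECISION_FOLD_GRID:
            raise ValueError(f"batch_precision_fold must be one of {PRECISION_FOLD_GRID}")


@dataclass
class SimTruth:
    """Ground truth for benchmark scoring."""

    is_dm: np.ndarray
    true_base_prop: np.ndarray
    batch_assign: np.ndarray
    condition_assign: np.ndarray
    mean_shift: float
    precision_fold: float
    shift_sign: np.ndarray = field(default=None)


@dataclass
class SimulatedDataset:
    counts: CountMatrixPair
    beta: BetaValueMatrix
    design: SampleDesign
    truth: SimTruth


def _balanced_design(n_samples):
    per_cell = n_samples // 4
    condition, batch = [], []
    for c in ("c1", "c2"):
        for b in ("B1", "B2"):
            condition += [c] * per_cell
            batch += [b] * per_cell
    return np.array(batch), np.array(condition)


def simulate_dataset(config=None, **kwargs):
    """Generate one dataset of counts, beta-values, design and truth.

    Fully deterministic given ``config.seed``.
    """
    if config is None:
        config = SimConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    f, s = config.n_features, config.n_samples
    batch, condition = _balanced_design(s)
    design = SampleDesign(
        sample_ids=[f"s{i + 1}" for i in range(s)], batch=batch, condition=condition
    )

    (a1, b1), (a2, b2) = config.mixture_shapes
    comp = rng.random(f) < 0.5
    base = np.where(comp, rng.beta(a1, b1, size=f), rng.beta(a2, b2, size=f))
    base = np.clip(base, 0.001, 0.999)

    dm_idx = rng.choice(f, size=config.n_dm, replace=False)
    is_dm = np.zeros(f, dtype=bool)
    is_dm[dm_idx] = True
    shift_sign = np.where(rng.random(f) < 0.5, 1.0, -1.0)

    in_c2 = condition == "c2"
    in_b2 = batch == "B2"
    p_cell = np.tile(base[:, None], (1, s))
    p_cell[is_dm[:, None] & in_c2[None, :]] += config.effect_pct / 100.0
    p_cell += (
        shift_sign[:, None] * (config.batch_mean_diff_pct / 100.0) * in_b2[None, :]
    )
    p_cell = np.clip(p_cell, 0.001, 0.999)

    phi_cell = np.where(
        in_b2[None, :],
        config.baseline_precision * config.batch_precision_fold,
        config.baseline_precision,
    ) * np.ones((f, 1))

    size = config.coverage_dispersion
    p_nb = size / (size + config.mean_coverage)
    coverage = rng.negative_binomial(size, p_nb, size=(f, s))
    while np.any(coverage == 0):  # floor at 1 read by redrawing
        zero = coverage == 0
        coverage[zero] = rng.negative_binomial(size, p_nb, size=int(zero.sum()))

    prop = rng.beta(p_cell * phi_cell, (1.0 - p_cell) * phi_cell)
    methylated = rng.binomial(coverage, prop)

    feature_ids = [f"f{i + 1}" for i in range(f)]
    counts = CountMatrixPair(
        feature_ids=feature_ids,
        sample_ids=design.sample_ids,
        coverage=coverage,
        methylated=methylated,
    )
    beta = counts.beta_values()
    truth = SimTruth(
        is_dm=is_dm,
        true_base_prop=base,
        batch_assign=batch,
        condition_assign=condition,
        mean_shift=config.batch_mean_diff_pct / 100.0,
        precision_fold=config.batch_precision_fold,
        shift_sign=shift_sign,
    )
    return SimulatedDataset(counts=counts, beta=beta, design=design, truth=truth)


def make_fig2_instance(seed=0, n_features=50):
    """An adversarial 20-sample instance for the Gaussian failure mode.

    Two categories: one centred near 0.5 (where a Gaussian approximation is
    adequate) and one pressed against the upper boundary, with a strong
    precision difference between the two batches in the boundary group.
    Gaussian adjustment of the raw beta-values provably pushes cells above
    1 here, while beta-model adjustment cannot leave (0, 1).
    """
    rng = np.random.default_rng(seed)
    s = 20
    # categories split samples 1-10 / 11-20; batches interleave both
    category = np.array(["mid"] * 10 + ["high"] * 10)
    batch = np.array((["B1"] * 5 + ["B2"] * 5) * 2)
    mu = np.where(category == "mid", 0.5, np.where(batch == "B1", 0.97, 0.82))
    phi = np.where(category == "mid", 30.0, np.where(batch == "B1", 400.0, 6.0))
    values = rng.beta(mu * phi, (1 - mu) * phi, size=(n_features, s))
    values = np.clip(values, 1e-6, 1 - 1e-6)
    matrix = BetaValueMatrix(
        feature_ids=[f"f{i + 1}" for i in range(n_features)],
        sample_ids=[f"s{i + 1}" for i in range(s)],
        values=values,
    )
    design = SampleDesign(
        sample_ids=matrix.sample_ids, batch=batch, condition=category
    )
    return matrix, design
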