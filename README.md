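# combatmet

Batch-effect correction for DNA methylation data under a beta-regression
model, with a count-level beta-binomial variant for bisulfite sequencing,
Gaussian ComBat baselines, a synthetic-data generator and a power /
type-I-error benchmark harness.

## The problem

DNA methylation is measured as **β-values** — the proportion of methylated
alleles at a locus, confined to (0, 1), typically skewed and bimodal.
Technical *batch effects* (bisulfite conversion runs, plates, platforms)
shift both the mean and the precision of β-values between sample groups and
can swamp biological signal. Classical ComBat assumes a Gaussian
location/scale model; applied directly to β-values it can push adjusted
values past 1 (or below 0), and applied to logit-transformed M-values it
mis-weights observations whenever the Gaussian approximation to a beta
distribution breaks down — exactly the boundary-adjacent, low-precision
loci where methylation data live.

## The model

For feature-wise observations `y_ij` (sample *j*, batch *i*) the package
fits, per feature, the beta regression

```
y_ij ~ Beta(mu_ij * phi_i, (1 - mu_ij) * phi_i)
logit(mu_ij) = alpha + X_j beta + gamma_i
var(y_ij)    = mu_ij (1 - mu_ij) / (1 + phi_i)
```

with one precision `phi_i` per batch and the identifiability constraint
`sum_i n_i gamma_i = 0` (sample-size weighted). Maximum likelihood is by
Fisher scoring with analytic score and expected information, vectorized
across features. The batch-free target distribution removes `gamma` on the
logit scale and pools precision by batch size,

```
logit(mu*_j) = logit(mu_hat_ij) - gamma_hat_i
phi*         = sum_i n_i phi_hat_i / sum_i n_i
```

and every observation is mapped to the value with the same quantile under
the batch-free beta distribution: `y* = F*^{-1}(F(y))`, an exact,
monotone inverse-CDF evaluation that cannot leave (0, 1). Covariate
effects `X_j beta` are part of `mu*` and survive adjustment. A
*reference-batch* mode instead adjusts every batch to the mean and
precision of a chosen batch, so new batches can be harmonized without
touching previously adjusted data. For bisulfite counts, the same
construction on a beta-binomial model maps each methylated count to an
integer in `[0, coverage]`, retaining the count nature of the data.

## Worked example

```python
import numpy as np
from combatmet import CombatMet, SimConfig, simulate_dataset
from combatmet import mvalue_lm_test, tpr_fpr, variance_explained

ds = simulate_dataset(SimConfig(batch_mean_diff_pct=10,
                                batch_precision_fold=5, seed=7))
res = CombatMet(ds.beta, ds.design).fit()
print(res.summary())
before = variance_explained(ds.beta, ds.design.batch)[1]
after = variance_explained(res.adjusted, ds.design.batch)[1]
print(f"mean batch R^2: {before:.4f} -> {after:.4f}")
pvals = mvalue_lm_test(res.adjusted, ds.design)
tpr, fpr = tpr_fpr(pvals, ds.truth, alpha=0.05)
print(f"TPR {tpr:.3f}  FPR {fpr:.3f}")
```

prints

```
ComBat-met batch adjustment
  features: 1000   samples: 20   batches: 2 (B1: n=10, B2: n=10)
  mode: cross-batch average   shrinkage: off
  adjusted features: 793   passed through (non-converged): 207
  median batch precision estimates: B1: 5.409, B2: 19.604
mean batch R^2: 0.2247 -> 0.1064
TPR 0.530  FPR 0.038
```

The simulated dataset injects a 10-percentage-point cross-batch mean shift
and a 5-fold precision difference (batch B1 at total precision 10, B2 at
50); the fitted per-batch precisions recover that ordering (the medians
sit below the injected beta-layer precisions because the binomial
counting layer adds dispersion on top). Features that are fully saturated
within a batch — every read methylated or unmethylated, common for loci
with base methylation near 0 or 1 — have no finite precision MLE and pass
through unadjusted, flagged in `per_feature_status`. Adjustment removes
half of the batch-explained variance (the rest is the precision
difference a mean-based R² only partly sees) while the differential test
on the adjusted data keeps its false positive rate at the nominal 5%
level and finds 53% of the truly differential features at N = 20.

The same objects are scriptable from the shell:

```sh
combatmet simulate --mean-diff 10 --fold 5 --seed 7 --out-prefix sim/
combatmet correct --beta sim/beta.tsv --design sim/design.tsv --out adj.tsv
combatmet test --beta adj.tsv --design sim/design.tsv --out pvals.tsv
combatmet benchmark --methods no_adjust,combat_met,mvalue_combat \
    --mean-diffs 0,10 --folds 1,5 --reps 50 --seed 1 --out bench.tsv
```

## Layout

| module | contents |
| --- | --- |
| `combatmet.data` | `BetaValueMatrix`, `CountMatrixPair`, `SampleDesign`, TSV I/O, β↔M transforms, boundary squeezing |
| `combatmet.betareg` | per-feature beta regression MLE (`BetaRegression`/`fit_feature`/`fit_all`), batched Fisher scoring |
| `combatmet.adjust` | `CombatMet` model + results, batch-free parameters, quantile matching, EB shrinkage |
| `combatmet.biseq` | beta-binomial fits, integer count adjustment, likelihood-ratio test |
| `combatmet.baselines` | Gaussian ComBat (raw-β and M-value), one-step design |
| `combatmet.simulate` | bisulfite-data generator with injected batch effects |
| `combatmet.diffmeth` | M-value linear-model test with variance moderation, TPR/FPR scoring |
| `combatmet.benchmark` | scenario grid runner, batch variance-explained diagnostic |
| `combatmet.cli` | `combatmet` command-line interface |
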