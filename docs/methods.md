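# Methods

## Model

Each methylation feature (probe, CpG site, region) is modelled
independently. A β-value `y_ij` for sample `j` in batch `i` is beta
distributed with mean `mu_ij` and precision `phi_i` in the
mean–precision parameterization (shapes `mu*phi`, `(1-mu)*phi`, so
`var = mu(1-mu)/(1+phi)`). The mean follows a logit-linear model

    logit(mu_ij) = alpha + X_j beta + gamma_i

where `X_j` holds the biological condition contrast and any numeric
covariates, and `gamma_i` is an additive batch effect on the M-value
(logit) scale. Precision is batch-specific because real batches differ in
measurement spread (platform, conversion chemistry), and this is the term
a location-only model misses. Identifiability uses the sample-size
weighted constraint `sum_i n_i gamma_i = 0`; with a reference batch the
model is reparameterized so `gamma_ref = 0` and `alpha` is the reference
batch mean.

Assumptions worth stating: observations are independent across samples
given the design (no kinship/repeated measures), each feature is
independent of the others (no spatial correlation along the genome), batch
and condition are not confounded (enforced as a rank check), and every
batch has at least two samples so its precision is estimable (enforced at
design construction).

## Estimation

Per-feature maximum likelihood by Fisher scoring on
`(alpha, beta, gamma_free, log phi_1..log phi_B)`: analytic score and
expected information of the variable-dispersion beta regression, starting
values from least squares of `logit(y)` on the mean design and a
method-of-moments precision per batch. Log-precision keeps `phi > 0`
unconstrained; the centering constraint is applied after fitting (fit with
a baseline batch, then shift `gamma` and `alpha`), which is algebraically
identical to the constrained optimum. Convergence is a relative
log-likelihood change below 1e-8, at most 200 iterations, with step
halving whenever a scoring step would decrease the likelihood.

Because every feature of a matrix shares the same design matrices, all
features are advanced jointly as batched small linear solves
(`(F, p, p)` systems), with per-feature convergence masks. This is
numerically identical to fitting features one at a time (tested to 1e-9)
and is what makes the 50-replicate benchmark cells run in minutes on one
CPU. `fit_all` processes features in fixed blocks of 64 so that results
are bit-identical for any `n_jobs`.

Failure handling: a feature whose precision MLE diverges (near-constant
values within a batch) or that exhausts iterations is flagged
non-converged — never an exception — and the adjustment passes it through
unchanged with a `passthrough_nonconverged` status. This pass-through is a
deliberately conservative choice: an unadjusted feature is recognizable,
a wrongly adjusted one is not. Missing cells (NaN) are dropped from that
feature's fit and stay NaN in the output.

## Adjustment

The batch-free distribution for sample `j` removes the batch term from the
fitted mean on the logit scale and pools precision across batches weighted
by batch size (`phi* = sum n_i phi_i / sum n_i`); in reference mode the
reference batch's mean and precision are adopted instead and
reference-batch data are (up to estimation error of the identity map)
unchanged. Each observation maps to
`y* = F*^{-1}(F(y; mu_hat, phi_hat); mu*, phi*)`.

Numerical choices:

- β-values are continuous, so the quantile match is an exact inverse of
  the regularized incomplete beta function (`betaincinv`), which is
  monotone in `y` and confined to (0, 1) by construction. A discrete
  nearest-CDF search is only needed for counts (below).
- CDF values are clamped to `[1e-12, 1 - 1e-12]` before inversion so
  squeezed boundary cells cannot map onto exactly 0 or 1.
- Boundary β-values (the beta likelihood is undefined at 0/1) are squeezed
  at load time: default `clip` to `[1e-6, 1 - 1e-6]` (idempotent,
  scale-free), alternatively the Smithson–Verkuilen compression
  `(y(n-1) + 0.5)/n`. Which cells were squeezed is recorded.
- Covariate effects `X_j beta` remain inside `mu*`, so biology is carried
  through the adjustment rather than removed and restored; for a
  logit-additive model the two are algebraically equivalent.

## Empirical-Bayes shrinkage (off by default)

A nonparametric Monte-Carlo scheme pools batch-effect estimates across
features, one batch at a time: for batch `i`, a feature's `(gamma_i,
phi_i)` is replaced by a weighted average over a seeded random donor
subset (default `min(F, 500)` features, self excluded), weighting each
donor by the beta likelihood of the feature's own batch-`i` data under the
donor's `(gamma_i, phi_i)` combined with the feature's batch-free mean.
The shrunk parameters define only the batch-free *target*; the source
distribution of the quantile map keeps the raw per-feature MLE. After
shrinkage the weighted-sum constraint is re-imposed.

Shrinkage is deliberately not the default: the beta likelihood already
accommodates skew and outliers, and pooling attenuates genuinely large
batch effects, leaving part of the batch signal in the data (visible in
the benchmark as more residual batch R², slightly lower power, and
below-nominal false positive rates). It exists for very small or noisy
studies where per-feature estimates are unstable, and because the full
Monte-Carlo over all features is expensive for large methylomes the donor
subset is capped.

## Count-level variant

For bisulfite counts `(k, n)` the same construction uses a beta-binomial
with logit mean model and per-batch overdispersion, parameterized by the
intraclass correlation `rho` through the precision `theta = (1 - rho)/rho`
(shapes `mu*theta`, `(1-mu)*theta`). Estimation is batched Newton with
analytic gradient and Hessian (chain rule through `(logit mu, log
theta)`), a Levenberg-style ridge and gradient-step fallback for
indefinite Hessians. The batch-free target removes `gamma` from the logit
mean and pools `theta` weighted by each batch's total coverage (the
count-level analogue of size-weighted precision pooling). Adjustment picks
the integer `k*` in `[0, n]` whose batch-free CDF is closest to the
observed count's estimated CDF — an exhaustive search over the support,
with CDF ties broken toward the original count for stability. Coverage is
never altered, so `0 <= k* <= n` always.

Downstream testing for counts is a likelihood-ratio test of the condition
effect between nested beta-binomial fits (pooled overdispersion) against
chi-square with (levels − 1) degrees of freedom. At N = 20 the asymptotic
reference is anticonservative, which the benchmark reproduces as inflated
false positive rates for the count-level workflow; the inflation shrinks
at larger N.

## Gaussian baselines

`gaussian_combat` is the classical location/scale empirical-Bayes batch
adjustment: feature-wise standardization against the batch-free mean and
the pooled full-model residual variance, per-batch location (`gamma`) and
scale (`delta`) estimates, moment-matched normal and inverse-gamma priors,
and the standard iterative posterior update to tolerance 1e-4 (at most 100
iterations). With EB on it follows the canonical implementation exactly
(batch variances with `n-1` denominators) and is cross-checked in the test
suite against Bioconductor's `sva::ComBat` via `Rscript` to ~1e-4. With
`eb=False` it is defined as exact per-batch location/scale standardization
(`n` denominators), which makes the no-op and closed-form-oracle
identities exact — useful as a test oracle. A single-batch design returns
the input unchanged. `naive_combat` applies this to raw β-values and
intentionally does not clamp its output: values beyond [0, 1] are the
failure mode the baseline demonstrates. `mvalue_combat` applies it to
logit-transformed M-values and back-transforms, which confines the output
but inherits Gaussian mis-weighting where the beta shape matters.

`onestep_design` instead builds the differential-model design with batch
indicator columns (intercept + condition + covariates + batch contrasts)
so batch is estimated jointly with the condition effect rather than
removed beforehand.

## Differential testing

Per-feature ordinary least squares of M-values on intercept + condition
(+ covariates, + batch indicators for the one-step route), t-testing the
condition coefficient. With moderation (default on) residual variances
are shrunk by the standard empirical-Bayes inverse-chi-square scheme: the
prior degrees of freedom `d0` and scale `s0^2` are moment-matched from the
log residual variances (digamma/trigamma matching, Newton inversion of the
trigamma), posterior variances are `(d0 s0^2 + d s^2)/(d0 + d)` and the
moderated t has `d + d0` degrees of freedom. Moderation rescales the t
statistic and never changes its sign. Benchmark scoring uses raw
`P < 0.05` (no multiplicity adjustment) because the quantities of interest
are per-feature error rates; Benjamini–Hochberg q-values are provided for
real-data use.

## Synthetic data

`simulate_dataset` emulates a bisulfite simulation study:

- 1000 features x 20 samples by default, balanced 2 conditions x 2 batches
  (5 samples per cell); 100 truly differential features with a +10
  percentage-point effect under condition 2.
- Per-feature base proportions from the bimodal mixture
  `0.5*Beta(0.6, 2.4) + 0.5*Beta(2.4, 0.6)` — real CpG methylation is
  predominantly low or high, rarely intermediate. Exact parity with any
  particular simulator's hyperparameters is a non-goal; the benchmark
  conclusions are checked under a perturbed mixture as a robustness test.
- Batch effects on the distribution level: batch 2 shifts the mean
  proportion by 0/2/5/10 percentage points (sign alternating per feature
  by a seeded coin flip, so both directions occur) and scales the beta
  precision by a 1/2/5/10 fold around the baseline precision 10; batch 1
  stays at baseline.
- Sampling layers: coverage ~ negative binomial (mean 30, dispersion size
  5, floored at 1 read by redrawing); the per-cell biological proportion ~
  beta with the cell's mean and batch precision; methylated count ~
  binomial(coverage, proportion); β = methylated/coverage, squeezed.
- True proportions are clamped to [0.001, 0.999] after all shifts, which
  attenuates injected effects for features near the boundaries — as
  saturation does in real data.

What the generator does *not* emulate: genomic autocorrelation between
neighbouring CpGs, coverage–methylation coupling, cell-type composition
effects, and array-specific artifacts (type I/II probe chemistry). Tests
passing on this generator therefore demonstrate correctness of the model
and adjustment machinery under the stated sampling scheme, not performance
on any particular platform's error structure.

`make_fig2_instance` constructs a small adversarial matrix — one sample
group centred at 0.5, one pressed against the upper boundary with a strong
cross-batch precision difference — on which raw-β Gaussian adjustment
provably exceeds 1 while the beta-model adjustment cannot.

## Benchmark harness

`run_grid` crosses mean shifts {0, 2, 5, 10}% with precision folds
{1, 2, 5, 10}. Within each replicate every requested method consumes the
same simulated dataset (paired design), then TPR/FPR are scored at
`P < .05` and summarized as medians (and IQRs) across replicates —
medians per replicate, then the median across replicates. Replicate seeds
derive from `SeedSequence([master_seed, scenario_index, replicate])`, so
runs are bit-reproducible and independent of parallelism or method
subsets. Default 50 replicates per cell keeps a full workstation run in
minutes; `--reps` scales it up.

`variance_explained` is the diagnostic used to quantify batch signal: a
per-feature one-way between/total sum-of-squares decomposition of
M-values over batch labels, averaged across features. Constant features
score 0 by convention.

## Known limitations

- The beta model is per-feature; it borrows no strength across the genome
  (by design — see shrinkage above) and ignores spatial correlation.
- Batch effects must come from *known* labels; latent-factor methods are
  the right tool when the source of variation is unidentified.
- The likelihood-ratio test downstream of the count-level variant is
  anticonservative at small N; treat its p-values cautiously below a few
  dozen samples per arm.
- Reference-batch Gaussian ComBat follows the canonical recipe
  (standardize to the reference, restore reference data exactly); its
  interaction with strong covariate effects inherits the usual ComBat
  caveats.
- Beta regression MLE needs variation within every batch; features that
  are essentially constant in a batch (e.g. fully saturated loci) pass
  through unadjusted. On the default generator's bimodal base
  distribution this affects a noticeable minority of features.
- The M-value t-test is mildly conservative on low-precision beta data
  even under a clean null (logit transforms make the tails heavy, which
  inflates variance estimates more than mean contrasts); the benchmark's
  false positive rates at baseline precision 10 sit slightly below the
  nominal 0.05 for every workflow, including no adjustment.
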