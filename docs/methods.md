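# Methods

## Estimand and estimator

The target is the average treatment effect among the treated (ATT) of a
binary exposure `A` on a continuous outcome `Y`, under no unmeasured
confounding. With propensity score `p(x) = P(A=1 | X=x)`, weighting by
the odds gives each exposed subject weight 1 and each unexposed subject
weight `p_i/(1-p_i)`, reweighting the unexposed group to the exposed
group's covariate distribution. The effect is then estimated by weighted
least squares of `Y` on an intercept and `A` alone — no covariate
adjustment, so that any benefit or harm of weight manipulation shows up
undiluted in the estimate. For a single binary regressor the WLS slope
is the weighted mean outcome difference

```
θ̂ = Σ w_i Y_i A_i / Σ w_i A_i − Σ w_i Y_i (1−A_i) / Σ w_i (1−A_i)
```

implemented in closed form (`AttWeightedOLS`) and verified against
statsmodels WLS to 1e-10 in the tests.

**Variance.** The default standard error is the model-based
(precision-weight) WLS one, `σ̂_w √(1/W_T + 1/W_C)` with
`σ̂²_w = Σ w e²/(n−2)` — exactly what `lm(y ~ A, weights = w)` reports.
Odds weights are not precision weights, so this SE is an approximation
whose coverage behaviour is itself one of the study's findings; an HC0
sandwich SE is available (`variance="sandwich"`). Confidence intervals
use Student-t with n−2 degrees of freedom. Both estimators are invariant
to rescaling all weights by a positive constant.

**Trimming.** Trimming (truncation) at percentile q replaces every
unexposed weight above the q-th quantile of the unexposed weight
distribution with that quantile (type-7 linear interpolation, the
default quantile in the major statistical stacks). Exposed weights are 1
by construction and are never modified. The studied grid is the 99th
down to the 50th percentile in 1% steps, plus 100 = untrimmed. The
reference population for the quantile is configurable
(`trim_reference: unexposed | all`); "unexposed" is the default because
the exposed weights are identically 1 and carry no distributional
information. Cutpoints are recomputed per simulated dataset, matching a
per-study analysis workflow. Re-trimming an already-trimmed set at its
own percentile is defined as a no-op (recomputing a type-7 quantile on
capped weights would interpolate strictly below the cap and violate
idempotence).

## Propensity estimators

* **Logistic regression** — maximum-likelihood fit on the 10 main
  effects only (statsmodels `Logit`). In scenarios 2 and 3 this model is
  structurally misspecified: it omits the true interactions and
  quadratic terms. Not clipped (MLE fitted probabilities are interior).
* **CART** — one `DecisionTreeClassifier`; the propensity is the treated
  fraction in a subject's terminal node. Defaults emulate classical
  recursive-partitioning settings: minimum split size 20, minimum leaf
  size 7; cost-complexity pruning off by default (scikit-learn's
  `ccp_alpha` is not on the same scale as classical `cp`, so parity
  cannot be claimed; the knob is exposed).
* **Random forest** — `RandomForestClassifier`, 500 fully grown trees,
  3 = ⌊√10⌋ candidate predictors per split, bootstrap resampling.
  Training-set probabilities are out-of-bag: fully grown trees memorize
  their in-bag samples, so the OOB decision function (which, with pure
  leaves, is numerically the OOB vote fraction) is the meaningful
  in-sample probability.
* **Boosted trees** — `GradientBoostingClassifier` (depth-3 trees,
  shrinkage 0.005, 50% subsampling, up to 10,000 trees by default). The
  number of boosting iterations is chosen by covariate balance, not by
  classification loss: at each grid point (every 100 iterations by
  default) candidate propensities are converted to ATT odds weights and
  the mean weighted Kolmogorov–Smirnov statistic across all 10
  covariates is computed; the returned fit is the first iteration
  attaining the minimum. The full balance path is kept in the fit
  metadata.

Tree-based raw probabilities can reach exactly 0 or 1; they are clipped
to [1e-3, 1−1e-3], which caps any single weight at 999 while leaving the
empirically observed weight range (maxima around 100–180) untouched.

The **weighted KS statistic** for covariate `x` is
`sup_t |F̂₁(t) − F̂₀(t)|` over the observed values, where each group's
ECDF is weighted and normalized by its group's total weight. The sup of
a step-function difference is attained at data points, so evaluating at
the pooled observed values is exact; ties are handled by evaluating only
at the last entry of each tied block. With unit weights this equals the
classical two-sample KS statistic (tested against a brute-force double
loop and `scipy.stats.ks_2samp`).

## The data-generating process

Each replicate has N = 500 subjects and 10 covariates drawn from a
multivariate standard normal with correlations (latent scale)
ρ(1,5)=0.2, ρ(2,6)=0.9, ρ(3,8)=0.2, ρ(4,9)=0.9. Covariates w1, w3, w5,
w6, w8, w9 are dichotomized at 0 (Gaussian-copula thresholding, so the
stated correlations hold before thresholding). w1–w4 are confounders,
w5–w7 affect exposure only, w8–w10 outcome only.

Exposure is Bernoulli in an inverse-logit score built from main effects
b = (0.8, −0.25, 0.6, −0.4, −0.8, −0.5, 0.7) on w1–w7 (intercept 0,
giving exposure probability ≈ 0.5 at the covariate means), plus
scenario-specific terms:

* scenario 1 — main effects only (additivity and linearity);
* scenario 2 — four two-way interactions (0.5b1·w1w3, 0.7b2·w2w4,
  0.5b4·w4w5, 0.5b5·w5w6) and one quadratic (b2·w2²);
* scenario 3 — ten interactions and three quadratics (b2·w2², b4·w4²,
  b7·w7²).

The outcome is linear: `Y = −3.85 + 0.3z1 − 0.36z2 − 0.73z3 − 0.2z4 +
0.71z8 − 0.19z9 + 0.26z10 − 0.4·A`, where `z` are the **latent
continuous** covariate values (`outcome_basis: latent`). The analyst
sees only the dichotomized w's, so the binary confounder indicators are
coarsened proxies for what actually drives the outcome. No separate
noise term is added by default; the seven covariate terms contribute
residual variance ≈ 1.4 on their own. Both choices are configuration
fields (`outcome_basis: observed`, `outcome_noise_sd > 0`) — with
`observed` basis and positive noise the generator is the textbook
all-observed linear model, under which adjusted OLS is exactly correct
(used as an oracle in the tests).

Why these two defaults: the exposure arm of the generator is pinned
tightly by published summaries of the resulting weight distributions
(our pooled unexposed-weight quartiles reproduce them to ±0.01 in all
three scenarios). The outcome arm is not directly pinned; among the
structural variants consistent with the simulation framework, the
latent-basis/no-noise configuration is the one that simultaneously
reproduces the untrimmed bias magnitudes, the untrimmed mean standard
error (0.101 vs 0.102 published), and the bias-optimal trim percentiles
(95 in scenario 2, ≈86 in scenario 3). It does not reproduce every
published coverage value (scenario 3's severe undercoverage in
particular), and the package reports its own computed values rather than
adjusting toward published ones.

**Seeding.** Replicate k of a study uses seed `base_seed + k`; each
stochastic fitting method receives a seed derived from (base seed,
scenario, replicate, method) via `SeedSequence`, so runs are exactly
reproducible, serial or parallel. A degenerate exposure draw (all 0 or
all 1, probability ≈ 2^−500 at these settings) triggers a logged redraw
from a derived seed, at most 10 times.

## Performance measures

Over R replicates with estimates θ̂₁…θ̂_R and truth θ = −0.4:

* **absolute percent bias** `100·|mean(θ̂) − θ|/|θ|` — the absolute
  value of the mean deviation, not the mean of absolute deviations (the
  latter is dominated by sampling noise even for an unbiased estimator;
  it is computed alongside as `mean_abs_percent_error`);
* **mean standard error** — the average of the per-replicate model SEs.
  Note one finding of the reconstruction: under trimming the mean
  *model* SE is nearly flat (trimming shrinks the unexposed weight total
  and the weighted residual variance at similar rates) while the
  *empirical* SD of the estimates falls sharply; diagnostics should look
  at both;
* **coverage** — the percent of replicates whose 95% CI contains θ
  (closed interval); always an exact multiple of 100/R;
* **weight diagnostics** — quartiles/maximum and the shares of weights
  ≥ 10 and ≥ 20, pooled over all unexposed weights across replicates
  (a distribution per scenario × method), plus the mean per-replicate
  sum of unexposed weights above their own 95th percentile (the "weight
  mass in the top 5%", about 12–13 subjects of ~250);
* **Spearman correlations** between methods' unexposed weights, computed
  per replicate and averaged (pooling ranks across replicates would mix
  dataset-level scale shifts into the ranks; pooled aggregation is
  available as an option).

The bias-optimal (or coverage-optimal) trim level is the grid argmin of
bias (or |coverage − 95|), ties going to the least-trimmed percentile.

## Problem sizes

The packaged full design is 3 scenarios × 4 methods × 51 trim levels ×
1000 replicates = 612,000 estimates. Propensity fitting dominates the
cost: the logistic arm runs in under a minute, but 500-tree forests and
10,000-tree boosting fits make the full four-method design a multi-hour
single-core computation. The test suite therefore exercises the
tree-based methods at reduced ensemble sizes (200-tree forests,
1000-tree boosting runs, 50 replicates per scenario) chosen so the
qualitative contrasts of interest (no trimming benefit for boosted
trees; boosted trees' scarcity of extreme weights) are far larger than
their Monte-Carlo error, and the acceptance script recomputes the
logistic-arm quantities at the full 1000 replicates.

## Known limitations

* The outcome arm of the generator is a reconstruction (see above); the
  published scenario-3 coverage (64.3%) and the nonzero trimmed-bias
  floors are not reproduced by any homoscedastic Gaussian outcome
  consistent with the validated weight distributions, and are left as
  documented discrepancies.
* Cross-ecosystem numeric parity for CART/forest/boosting is not
  attainable (different default stopping/pruning rules); those methods
  are evaluated on qualitative patterns.
* Only high-weight truncation is implemented; raising small weights,
  weight stabilization, doubly-robust augmentation, and matching or
  stratification uses of the propensity score are out of scope.
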