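# Methods

## The problem and the study design

Most comparisons of machine-learning and regression methods for clinical
prediction are empirical: fit everything on one dataset, report who won.
That confounds the methods' properties with the (unknown) data-generating
process of that one dataset. The design implemented here inverts this:
each candidate method is, in turn, *made* the truth. A method is fit once
to a base derivation sample; its fitted prediction surface plus resampled
residuals define a data-generating process (DGP); every method is then
fit to each simulated derivation sample and scored on a simulated
validation sample. Because the generating method is known, each method's
performance can be read relative to the method that generated the data.

The clinical setting is prediction of systolic blood pressure at hospital
discharge (mmHg, continuous) in two disease cohorts: acute myocardial
infarction (AMI; derivation n = 8145, validation n = 4444, 33 candidate
predictors) and congestive heart failure (CHF; 7156 / 6818, 28
predictors). Derivation and validation samples come from different
calendar periods, so validation-set performance is external (temporal)
validation, not resampling.

## Synthetic cohorts

The real cohorts are access-restricted; only marginal summaries are
published. The generator reproduces those marginals exactly in
expectation and fills the unpublished joint structure with an explicit,
documented stand-in:

- **Covariates** are drawn through a Gaussian copula: a latent
  multivariate normal z with correlation matrix C; continuous column j is
  μⱼ + σⱼzⱼ, binary column j is 1{zⱼ > Φ⁻¹(1 − πⱼ)}. The packaged AMI and
  CHF configurations carry every published variable (type, per-role mean ±
  SD or prevalence). The one cell censored at source (cardiogenic shock,
  AMI validation, count ≤ 5) is imputed at 0.5% prevalence and flagged
  `imputed`.
- **Correlation** C defaults to exchangeable ρ = 0.2 on the latent scale.
  No inter-predictor correlations are published, so this is a stand-in
  chosen to be qualitatively realistic for clinical covariates (weak
  positive dependence), not an estimate; a full matrix can be supplied.
- **Continuous marginals** are Gaussian by default. Skewed laboratory
  values (e.g. creatinine) can be switched to a moment-matched lognormal
  per variable (`lognormal: true`), but the default stays Gaussian: the
  framework's comparisons concern prediction machinery, not marginal
  shape, and Gaussian marginals keep the calibrated truth exactly linear.
- **Reference outcome.** The real study observes the outcome; the
  synthetic study needs a known truth. `calibrate_outcome_model` draws raw
  coefficients reproducibly from the seed (standard normal scaled by each
  predictor's marginal SD so every variable contributes comparably),
  rescales them by one common factor and picks the intercept so that, on
  the generated covariates, the outcome mean equals the published mean and
  the linear predictor explains a chosen **signal fraction** of the
  published variance; independent Gaussian noise supplies the remainder.
  The default signal fraction is 0.2, matching the magnitude of validation
  R² (~0.16–0.24) reported for these cohorts, so synthetic runs live in a
  realistic signal regime. The signal fraction is the theoretical R²
  ceiling of the cohort, which makes oracle tests possible.

What passing tests on these cohorts do *not* show: behavior under real
covariate dependence (interactions, nonlinear dependence, skewness) or
under a non-linear true outcome surface. The factorial simulation
addresses the latter by using fitted tree/network anchors as truths.

## The six learners

All methods use every predictor as a main effect and share one
fit/predict contract (`LearnerSpec` → `FittedLearner`).

- **ols_rcs** — linear regression by least squares with each continuous
  predictor expanded in a restricted cubic spline basis (binary
  predictors enter as single columns). The basis is the standard
  truncated-power natural-spline form: k knots give k − 1 columns
  (identity plus k − 2 cubic contrasts), linear beyond the boundary
  knots; knots sit at the conventional default quantiles (k = 3:
  10/50/90%, ..., k = 7). One shared knot count k applies to all
  continuous predictors. σ̂² = RSS/(n − p) (the unbiased variant) is
  stored for the Gaussian DGP. Rank deficiency and n ≤ p are reported as
  errors, never silently regularized.
- **lasso / ridge** — penalized least squares on predictors standardized
  to unit variance (population SD, the path-algorithm convention),
  intercept unpenalized, with the path parameterization
  (1/2n)RSS + λ‖β‖₁ and (1/2n)RSS + (λ/2)‖β‖₂². Coefficients are mapped
  back to the original scale. Backed by scikit-learn's coordinate descent
  (`Lasso`, `lasso_path`) and `Ridge`; λ = 0 falls back to exact least
  squares.
- **boosted_trees** — stagewise gradient boosting with squared-error
  loss, tree depth = interaction depth, fixed tree count (default 100, no
  early stopping), via `GradientBoostingRegressor`. No subsampling by
  default, which makes the fit deterministic given the data; a
  `subsample` option restores stochastic boosting. A zero learning rate
  is handled exactly: the stagewise recursion never leaves the initial
  constant, so predictions are the training mean.
- **random_forest** — `RandomForestRegressor` with mtry candidate
  predictors per split, a minimum leaf size, and 500 trees by default;
  split ties are handled by the library's seeded feature permutation.
- **nnet1** — a single-hidden-layer feed-forward network with logistic
  hidden units and a linear output, fit in-package by L-BFGS on the
  penalized least-squares criterion Σ(yᵢ − f(xᵢ))² + decay·‖w‖² (decay
  applies to all weights and biases, mirroring the classical weight-decay
  formulation). Inputs are standardized; initial weights are
  Uniform(−0.5, 0.5) from the seed, except the output bias, which starts
  at mean(y) — with a raw mmHg outcome an O(1) start puts the optimizer
  needlessly far from the optimum. Max 500 iterations, tolerance 1e-8,
  single start. A `linear_hidden` switch gives fully linear hidden units.
  A single hidden layer suffices for this function class; deeper nets are
  out of scope.
- **intercept_only** — diagnostic baseline (training-mean prediction);
  not one of the compared methods.

Fitted learners serialize to a versioned JSON container (method,
hyperparameters, schema, state; sklearn estimators embedded as base64
pickle) so a DGP can be rebuilt; round-trip equality is tested for all
six methods.

## Tuning

Tenfold cross-validated grid search: folds are drawn once per search from
a seeded permutation (sizes differ by at most one; not stratified — the
outcome is continuous) and reused at every grid point. The fold score is
the squared Pearson correlation on the held-out fold — the same statistic
as final evaluation, for uniformity; a zero-variance fold is recorded as
0 with a warning. The winner maximizes the K-fold mean; ties break to the
earliest point in declared grid order. Default grids: network H ∈ 2..15 ×
decay ∈ {0, 0.01, 0.05, 0.1, 0.5}; boosting depth ∈ 1..5 × rate ∈
{0.005, 0.01, 0.035, 0.065, 0.1}; forest mtry ∈ ⌊p/6⌋..⌊p/2⌋ × node size
∈ {5, 10, 20, 50}; splines k ∈ {3, 4, 5, 6}. The tree/forest ranges are
chosen to bracket the shipped tuned values (depth 4, rate 0.065, mtry
6/8, node size 20).

For the penalized linear models, `select_lambda` builds a 100-point
log-spaced path from λ_max (smallest λ zeroing every lasso slope,
max|Z'y|/n; ridge uses the conventional 1000× analog) down to 10⁻⁴λ_max
and minimizes tenfold CV MSE, with per-fold re-standardization. The
minimum-CV rule is the default ("optimal λ"); the one-SE rule is behind a
flag.

Hyperparameters are tuned **once** on the base data and frozen across all
simulation replicates — the tuned point is "selected for all subsequent
applications" — with per-replicate re-tuning available only as an
explicit sensitivity option.

## The DGP engine

Per anchor: fit once on the base derivation sample; bootstrap-expand the
validation covariates to 100,000 rows (removing evaluation noise from the
external estimate); compute ŷ on both. Residual pool = y − ŷ on the
derivation sample (empirical mode); the OLS-spline anchor instead draws
N(0, σ̂²). Covariates are frozen across replicates; only outcomes are
re-simulated, with independent substreams for derivation and validation
draws and one substream per replicate, so replicate r is reproducible in
isolation.

Validation-sample noise is drawn from the **derivation** residual pool:
residuals are defined against observed derivation outcomes, and reusing
the pool keeps the noise law identical in both samples. Whether the
original protocol instead built a second pool from observed validation
outcomes is ambiguous; `build_dgp(validation_pool=True)` implements that
alternative.

The DGP's **signal proportion** var(ŷ_valid)/(var(ŷ_valid) + var(noise))
is exposed as the closed-form R² ceiling. Two oracle facts are tested:
the anchor's *own* predictions achieve the ceiling in mean (equality
within Monte Carlo error), while a per-replicate *refit* sits at or below
it — at n = 1000 with ~46 design columns, refit estimation error costs
roughly 0.03 in R², which is why the refit check is one-sided.

Parameter recovery: refitting the OLS-spline model on simulated
derivation samples is exactly unbiased for the anchor's coefficients, so
the standardized biases (bias / Monte Carlo SE over 200 replicates)
behave like iid N(0,1) draws. The acceptance check is therefore joint —
RMS standardized bias below 2 with a per-coefficient Bonferroni-scale
guard at 4.5 — rather than a per-coefficient 2-SE rule, which would fail
with high probability under its own null once ~46 coefficients are
tested.

## Evaluation and reporting

R² is reported as a proportion in [0, 1] throughout; percent formatting
is presentation-only. MSE is in mmHg², MAE in mmHg; MAE² ≤ MSE (Jensen)
is asserted globally. Summaries are mean ± SD over replicates with the
n − 1 denominator (the convention with 1000 replicates; the choice is
immaterial at that count). A failed fit (e.g. optimizer non-convergence)
is logged and excluded from means; the summary's count column makes
omissions visible. R² against an exactly constant prediction vector is
undefined and treated as a failure, not a zero.

## Problem sizes

The shipped `desk` preset runs the factorial study at n_derivation =
1000, validation expanded to 5000, R = 50 replicates — the package's
choice of a size at which every oracle property is testable interactively
while the Monte Carlo error bars remain small enough to be informative.
The `full` preset carries the replication-scale conditions (published
cohort sizes, expansion to 100,000, R = 1000). Test-suite checks use the
desk scale or smaller.

## Known limitations

- The copula correlation and the linear reference truth are stand-ins;
  conclusions about the *relative* behavior of methods under the anchored
  DGPs are the supported use, not estimates of real-cohort performance.
- Empirical-pool residual draws are iid per subject: no heteroscedastic
  or covariate-dependent noise.
- The shipped tuned hyperparameters are fixed configuration defaults; on
  synthetic cohorts a fresh grid search may select different values.
- Lasso/ridge λ values are on the standardized path scale described
  above; λ values from other parameterizations must be converted.
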