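# Methods

## The model

`pagsem` implements a generalized structural equation model (GSEM) for the
association between physical-activity behaviour and obesity in adult survey
data. Two latent dimensions are measured by weekly minutes spent on six
activities:

* **Screens use** (L1): computer/smartphone (reference), television,
  video games;
* **Active transportation** (L2): motor-vehicle transport (reference),
  cycling, walking.

The three sub-models share one joint likelihood:

1. **Measurement model.** Each indicator time t_j is Weibull with shape k_j
   and scale exp(kappa_j + lambda_j L), an accelerated-failure-time form on
   the log scale. The Weibull family matches the right-skewed shape of
   weekly-minute data. The reference indicator of each latent has its
   loading fixed at 1, so other loadings read as signal ratios to the
   reference; the latent residual variances are free (Stata-style
   identification).
2. **Structural model.** (L1, L2) are bivariate normal with free residual
   covariance Psi and means gamma_1*PA and gamma_2*PA, where PA is
   leisure-time physical activity in minutes/week.
3. **Disease model.** Obesity (BMI >= 30) is Bernoulli with a log link:
   log pi = alpha + beta_1 L1 + beta_2 L2 + x'beta over sex, age, ethnicity,
   schooling, wealth quartile, energy intake and leisure-time PA.
   Exponentiated coefficients are prevalence ratios (the "modified Poisson"
   reading); the sandwich covariance provides the robust variance. A
   Poisson pseudo-likelihood for the binary outcome is available as a
   configuration alternative, but the default is the proper Bernoulli-log
   density, which the joint latent likelihood requires.

Each person's marginal likelihood integrates the product of the six Weibull
densities, the outcome probability and the latent prior over R^2.

## Estimation

* **Quadrature.** Adaptive Gauss-Hermite: per person, a damped Newton
  search finds the posterior mode of the integrand (the mode search
  restarts from the prior mean when a warm start is not competitive,
  because Newton creeps on the double-exponential Weibull tail), and the
  grid is recentred/rescaled by the mode curvature. The default is **15
  nodes per dimension**. Nine nodes reproduce the log-likelihood *value*
  to ~3e-5 relative but visibly bias the loading estimates when
  |k·lambda·sigma| is around 3 (as it is here: the video-game and cycling
  indicators are near-direct measures of their latents), so the package
  default is deliberately higher than the smallest node count that looks
  stable on the likelihood value. One-dimensional (single-latent) fits use
  21 nodes in the full-scale recovery runs (they are cheap); the
  full-scale joint fit uses 13 nodes per dimension, where the recovered
  parameters agree with 15-node fits well within sampling error at a
  fraction of the cost.
* **Frozen-adaptation outer loop.** Re-adapting the grid at every
  evaluation makes the objective and the posterior-expectation score
  mutually inconsistent at the quadrature-error level, which stalls
  quasi-Newton optimizers. The fitter therefore freezes the adaptation,
  optimizes the frozen-grid objective (whose *exact* gradient is the
  posterior-expectation score), re-adapts at the new parameters, and
  repeats to the fixed point — the standard scheme for adaptive-quadrature
  mixed models. Convergence is declared on the frozen-grid gradient
  (5e-4 per unit weight, 10x the inner tolerance) together with outer-loop
  parameter stability.
* **Optimizer parameterization.** The optimizer works on a standardized
  parameterization (unit-variance latents; the reference indicator's signal
  SD becomes a free log-parameter; other loadings enter as signal scales
  lambda_j*sigma). This removes the strongly curved lambda*sigma ridge that
  appears when the reference indicator is a weak measure of its latent
  (sigma_L1 = 0.1 against a log-scale noise SD near 1). Estimates and
  covariances are reported on the reference-loading-1 basis. Covariate
  columns are rescaled to unit SD internally. Inner optimization is
  L-BFGS-B (generous box bounds keep every evaluation finite) followed by
  damped scoring steps with the BHHH (outer-product-of-scores) metric.
* **Starting values** are deterministic: marginal Weibull fits for
  intercepts and shapes; closed-form method-of-moments for loadings and
  latent variances from the covariance of log indicator times
  (cov(y_i, y_j) = lambda_i lambda_j sigma^2 with the reference loading 1);
  least squares for the structural coefficients; a latent-free log-link
  fit (solved nearly exactly) for the disease coefficients.
* **pi >= 1 handling.** The linear predictor passes through a smooth
  soft-min cap at -1e-8 (log-sum-exp, sharpness 200) so the Bernoulli
  density stays proper; the cap is inactive to machine precision below
  about -0.1, which covers essentially every observation in realistic
  configurations.
* **Covariances.** Model-based: inverse observed information by central
  finite differences of the analytic score on the frozen grid, inverted in
  the standardized basis and mapped to the reporting basis by the delta
  method (exact at a stationary point). Eigenvalues of the information are
  taken in absolute value with a relative floor before inversion: a weakly
  identified direction whose measured curvature is dominated by
  quadrature/finite-difference error then yields a large finite variance
  instead of a spurious failure; a grossly indefinite matrix still raises.
  Robust: sandwich A^{-1} B A^{-1} with B the weighted outer product of
  per-person scores. Weights (expansion factors) multiply per-person
  log-likelihood contributions; duplicating records at proportionally
  reduced weight leaves the likelihood identical to machine precision and
  the estimates identical to optimizer tolerance.
* **AIC/BIC** use the free-parameter count and the unweighted person count.

## Synthetic data

The generator emulates the target survey's structure so that every pipeline
stage is testable without microdata. Defaults are the study conditions:

| quantity | default | source/rationale |
|---|---|---|
| n_persons | 9,658 | analysis sample size |
| female share | 0.562; age truncated-normal 38.5±13.1 on [18,64] | reported margins |
| ethnicity afro/indigenous/other | .071/.020/.909 | reported margins |
| schooling primary/secondary/tertiary | .158/.753/.089 | reported margins (normalized) |
| wealth quartiles | .295/.237/.244/.224 | reported margins |
| loadings | TV 3.9, video games -20.3, cycling -5.4, walking 0.8 | published point estimates |
| indicator scales | exp intercepts 45/420/30/140/20/70 min/week | published medians |
| Weibull shapes | 1.3 (all) | plausible skewness; not reported |
| latent SDs | 0.1 (screens), 0.5 (transport); corr 0.2 | scale not reported; fixed by the recovery design |
| gamma_1, gamma_2 | -0.00098, 0.00424 per min/week | 0.00424 published via the indirect product; -0.00098 back-solved from the published screens indirect effect |
| disease PRs | female 1.71, age 1.02/yr, afro 1.36, indigenous 1.09, Q2 1.23, Q3 1.13, Q4 1.04, energy 1.00, leisure-PA 0.9996, screens 1.19, transport 0.86 | published table |
| schooling coefficients | +0.05 secondary, -0.10 tertiary (log scale) | not reported; small plausible values |
| intercept | calibrated so mean capped-probability = 0.191 | published prevalence; root-found on the realized linear predictors |
| energy intake | log-normal, median 2000 kcal/day, log-SD 0.3 | typical adult intake |
| leisure PA | 35% zeros, else gamma(1.3, scale 120) min/week | plausible zero-inflated activity distribution |
| departments | 33 DIVIPOLA-style codes, decaying multinomial | makes spatial summaries non-degenerate |
| department shifts | prevalence N(0, 0.1) on the log scale; transport-latent mean N(0, 0.15) | configurable heterogeneity |
| expansion factors | 1 (self-weighted); gamma option | real weights unavailable; weighting is a contract |

BMI is generated conditionally on the Bernoulli obesity draw (obese:
30 + gamma; non-obese: 18.5-30 beta-scaled) so the BMI >= 30 flag and the
modelled outcome agree for every record; the Bernoulli draw is the analysis
truth. Probabilities that would exceed 1 are capped with a logged capped
fraction (< 0.1% under defaults, ~2e-5 in practice).

What the generator does **not** emulate: the survey's multistage stratified
sampling, cluster structure and non-response adjustment; questionnaire
measurement error; reporting heaping (e.g., times rounded to 30 minutes);
true zeros in indicator times (draws are strictly positive; real-data
ingestion shifts zeros to 1 minute, switchable in principle to
left-censoring). Passing tests therefore show the estimator is correct
under the model's own assumptions, not that the model is correct for any
particular survey.

## Identifiability of the latent scale

With the reference loading fixed at 1, the latent SD is identified only
through the reference indicator's covariances with its siblings. For the
screens dimension (sigma = 0.1, noise SD ~0.99) this information is weak:
at n = 20,000 the sampling SD of the TV loading is about 0.3 and of the
video-game loading about 1.5, almost entirely driven by sigma-hat. The
loading *ratios* (and products lambda*sigma) are estimated an order of
magnitude more precisely. Recovery checks on these loadings are therefore
genuinely stochastic at the study scale.

## Diagnostics, scores, summaries

* Distribution selection fits Weibull/gamma/log-normal/exponential by ML
  (location 0) and ranks by AIC, with KS statistics against the fitted
  CDFs. Correlation matrices use log(time + 1) by default (the scale on
  which the measurement model is linear), Spearman optional. KMO uses
  anti-image partial correlations from the inverse correlation matrix;
  Bartlett's statistic is -(n - 1 - (2p+5)/6) ln det R. Exploratory
  loadings use principal-axis factoring (iterated communalities) with
  varimax rotation and a deterministic sign convention.
* Empirical-Bayes scores are posterior means/SDs from the same adaptive
  quadrature, conditioning on indicators, covariates and (by default) the
  outcome; indicator-only conditioning is a flag. Tertiles use type-7
  quantiles, left-closed; a constant score distribution yields all-"low"
  with a warning. Weighted quantiles are available but unweighted is the
  default.
* Department summaries compute expansion-factor-weighted prevalence
  (logit-Wald intervals on the Kish effective n), unweighted median
  adherence per latent, and rank-based quartile bins with deterministic
  tie-break by department code (group sizes differ by at most one); tables
  with fewer than four departments carry no bins. Output is a join-ready
  attribute table; rendering is left to GIS tools.
* Descriptive comparisons use unweighted Pearson chi-square (no design
  correction — none is claimed) and the two-sided Mann-Whitney U with tie
  and continuity corrections.

## Problem sizes used in the test-suite and acceptance runs

Full-scale recovery runs use n = 20,000 (measurement models at 21 nodes,
the joint model at 13 nodes per dimension); interval-coverage uses 200
replicates at n = 2,000 (latent-free); oracle equivalences use n <= 50
with 100,000 Monte-Carlo draws per person or a 10,001-point grid; unit
tests use n between 20 and 6,000. These sizes were chosen so each check is
statistically informative for the quantity it probes.

## Known limitations

* Latent dimension count is limited to two (the study design); the
  quadrature and Cholesky algebra are specialized accordingly.
* The frozen-grid AGQ estimate carries the usual O(quadrature-error) bias;
  at 15 nodes/dimension this is far below sampling error at the study
  sizes, but very sharp measurement regimes would need more nodes.
* Missing data are not modelled: complete cases only, matching the study's
  exclusion design.
* The indirect effects are path products, not counterfactual mediation
  estimands.
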