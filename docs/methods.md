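# Methods

## The model

`mifs` is built around a linear Gaussian state-space model for intensive
longitudinal data — a process factor analysis (PFA): p manifest indicators
load on q latent factors whose dynamics follow a first-order vector
autoregression with exogenous covariates,

    eta[i,t] = alpha + F eta[i,t-1] + B x[i,t] + zeta[i,t],   zeta ~ N(0, S_zeta)
    y[i,t]   = tau + Lambda eta[i,t] + A x[i,t] + eps[i,t],   eps ~ N(0, S_eps)
    eta[i,1] ~ N(mu_eta1, S_eta1)

for persons i = 1..N at equally spaced occasions t = 1..T_i.  One loading
per factor is fixed at 1 for identification; S_eps is diagonal (no
correlated measurement errors); all parameters are time-invariant and shared
across persons.  The bundled presets use the bivariate two-factor,
six-indicator configuration with AR coefficients 0.5 ("low") or 0.7
("high"), cross-regressions (-0.2, -0.3), covariate effects
(0.3, 0.5; -0.3, -0.4) of one binary and one continuous covariate, process
noise covariance [[2, .5], [.5, 6]], intercepts 3, free loadings (2, 1, 2, 1)
and unit error variances.

Assumptions worth keeping in mind: linearity and Gaussian noise, equal
spacing in time, parameter homogeneity across persons (no random effects),
and a correctly specified factor structure.

## Estimation

The log-likelihood is the prediction-error decomposition: the Kalman filter
yields one-step-ahead prediction errors and their variances, whose Gaussian
log-densities sum over persons and occasions.  Because S_eps is diagonal,
the filter processes the indicators of an occasion one at a time as scalar
updates (the univariate treatment); this is algebraically identical to the
joint update, needs no matrix inversion, and handles partially missing
occasions by skipping the missing rows — full-information maximum
likelihood over the observed cells.  Fully missing occasions contribute a
time update only.  Occasions with a missing *covariate* (when the model uses
covariates) are excluded from the likelihood and the remaining rows treated
as consecutive; the count of excluded rows is reported.  The recursions are
compiled with numba; the per-evaluation cost for a 30 x 100 x 6 panel is
under a millisecond, which is what makes the Monte Carlo harness tractable
on one CPU.

Optimization is quasi-Newton (L-BFGS-B) with finite-difference gradients on
a transformed scale: log for the measurement-error variances, a Cholesky
parameterization for the process-noise covariance, and unconstrained
transition/regression entries.  Stability of the transition matrix is not a
hard constraint; during optimization the initial-state distribution is tied
to the stationary solution implied by the current (F, S_zeta) — with mean
(I - F)^-1 (alpha + B xbar) — so a spectral radius >= 1 acts as a barrier,
and the fitted F is checked afterwards.  Starting values are moment-based:
indicator means for tau, ones for free loadings, half of each observed
variance assigned to measurement error and half (via the anchor indicators)
to the process noise, 0.1 for dynamic coefficients.  Up to a configurable
number of jittered restarts run if the optimizer does not report
convergence.  Standard errors come from the inverse of a central-difference
numerical Hessian of the negative log-likelihood with respect to the
*natural* parameters, so they are directly comparable to the generating
values; a non-positive-definite Hessian marks SEs unavailable rather than
failing the fit.

Tunables (defaults): gradient tolerance 1e-6; restarts 3; Hessian step
1e-4 relative.  The Monte Carlo studies in the test-suite run with gradient
tolerance 1e-4 and one restart — point estimates move at far below the
precision of any summarised quantity.

Factor scores are the fixed-interval (Rauch-Tung-Striebel) smoothed means
E[eta_t | y_1..T_i] at the ML estimates of a covariate-free model fit to the
*incomplete* panel.  With F = 0 the smoother reduces exactly to the
regression factor-score formula, which the tests assert to 1e-8.  Scores
are defined at every occasion, including fully missing ones (where they are
the model-implied conditional path).

## Missingness generation and calibration

Two nonignorable mechanisms mask a complete panel through a logistic model
logit P(R=1) = phi0 + phi1 z1 + phi2 z2 + phi3 * driver with fully observed
auxiliaries z1, z2 ~ Uniform(-3, 3).  Under *item-dependent* missingness
the driver is the cell's own value (phi3 = -0.6 for the first indicator
block, +0.6 for the second, -0.8 for covariates); draws are independent per
cell, so missingness scatters across items.  Under *factor-dependent*
missingness the driver for an indicator is its factor's true latent value
and a single Bernoulli draw per (person, occasion, factor) masks the whole
indicator block — the simultaneous-missingness signature; covariates still
follow the item rule.  MAR variants with random location indicators and a
composite-driven variant (for the misspecified-factor-structure scenario)
are also provided.

The intercepts phi0 are calibrated per target variable by monotone
root-finding so the *expected* missingness rate — the mean logistic
probability — over a dedicated reference panel (200 persons x 200
occasions, fixed calibration seed) equals the 30% target; calibrating on a
large reference rather than the analysis panel keeps phi0 from adapting to
a single replication's noise.  Out-of-sample empirical rates land within
±0.02 of target.  McKelvey-Zavoina pseudo-R² diagnostics are reported in
two variants (variance share of the full linear predictor, and each term as
a sole predictor) since either convention is defensible.

## Chained-equations imputation

The engine is a fully-conditional-specification (MICE-style) Gibbs sampler.
Continuous targets use predictive mean matching: a Bayesian linear
regression draw on the observed cases (type-1 matching: observed cases
predicted with the posterior mode, missing cases with the parameter draw),
then each missing cell receives the observed value of one of k = 5 donors
with the closest predicted mean (k is not fixed by the method's
description; 5 is the common default).  Binary targets use an IRLS logistic
fit with a normal posterior draw of the coefficients and a ridge (1e-5)
fallback under separation.  Predictor pools hold the other analysis
variables, the frozen factor scores, lag-1 columns of all of these
(optionally lead-1), missingness indicators R_* (never a variable's own
indicator), and the auxiliaries.  Columns that are constant or exact
duplicates on a target's observed rows — e.g. sibling indicators under
block missingness — are structural degeneracies and are dropped once per
chain.

Lag and lead columns are imputed as variables in their own right rather
than being re-derived ("passively synced") from the working values each
iteration.  Both variants are implemented (`sync_lags`), but passive
syncing closes a feedback loop through time that gives the Gibbs chain a
near-unit-root component: chain-level means then carry initial offsets for
60+ iterations.  Treating lags as ordinary columns — which is also how a
practitioner hands lagged variables to a chained-equations package — cuts
that loop.  The price is that the completed data matrix is not forced to be
internally consistent between a variable and its lag column; completed
panels keep only the analysis columns, so this never leaks into the fitted
model.

Chains are initialized by sampling each incomplete column's observed values
with replacement; each of the m chains has its own seeded substream; visits
run over dependent variables in column order, then covariates, then lag
columns, refitting each univariate model against current working values.
Convergence is summarised by the potential scale reduction factor computed
per variable across the m chains, with the *imputed values over the
retained (second-half) iterations* as each chain's draws:

    rhat = sqrt( ((n-1)/n W + B/n) / W )

where W is the mean within-chain variance of the draws and B = n Var(chain
means).  The within-chain moments are reconstructed exactly from the
per-iteration (mean, sd, count) traces.  Values are floored at 1.  An
alternative — treating the per-iteration chain *means* as the draws — is
far more conservative: the chain mean of this Gibbs system moves slowly
(see above), so that statistic stays well above 1.1 at 30 iterations for
any engine of this family we tried, including an independent implementation
(statsmodels' MICE) on the identical design matrix.  The pooled-draw
definition matches the usual description of the diagnostic and reproduces
the expected "converged within 30 iterations" behaviour; the trace table is
persisted so either statistic can be recomputed.

## Missing-data handling pipelines and pooling

* **LD** — drop occasions with any missing covariate (rows with missing
  dependent variables only are kept for FIML), renumber the remaining rows
  as consecutive, fit once; z-based 95% CIs.  Refuses to run if fewer than
  10% of rows remain.
* **MI-MV** — chained equations over dependent variables and covariates
  (no factor scores); fit each completed panel; pool.
* **PMI-MV** — as MI-MV, but the imputed dependent-variable values are
  discarded before each fit (original y missingness restored and handled by
  FIML); only covariate imputations differ across fits.  When covariates
  are complete this collapses to a single fit identical to LD.
* **MI-FS** — factor scores estimated from the incomplete panel enter the
  predictor pools along with their lags; otherwise as MI-MV.  A
  non-convergent factor-score stage aborts the pipeline.

Pooling follows the usual combining rules: Qbar = mean estimate, W = mean
squared SE, B = between-imputation variance, T = W + (1 + 1/m) B,
SE = sqrt(T).  Degrees of freedom use the Barnard-Rubin small-sample
formula with complete-data df = n_used - k; CIs are t-based for pooled fits
and z-based for single fits.  With zero missing cells every pipeline
short-circuits to the single complete-data fit, which makes the
all-methods-agree property exact rather than optimizer-tolerance-limited.
Per-imputation fits warm-start from the factor-score-stage estimates
(MI-FS), from the LD fit of the same masked panel when available in the
evaluation harness, or from the first imputation's fit — initialisation
only; it does not change the optimum, only the time to reach it.

## Monte Carlo harness

`run_condition` loops replications of {simulate -> fit complete benchmark ->
mask -> handle -> pool} with a deterministic seed schedule (replication h
uses master_seed + h) and a paired design: all methods in a replication
consume the identical masked panel.  Summaries per (condition, method,
parameter): bias, relative bias (absent when the truth is 0), mean
estimated SE, Monte Carlo SE (sd of estimates, divisor H-1), RMSE, dSEfull
(mean SE minus the complete-data benchmark's mean SE), power (CI excludes
0) and coverage (CI contains the truth), the last two in percent.  The
algebraic identity rmse² = bias² + ((H-1)/H) mcse² holds exactly and is
asserted to 1e-12.  Nonconvergent replications are excluded per method with
reported counts.  Parameters aggregate into the reporting groups d_ar,
d_cr, d_x1, d_x2, d_var, d_cov, m_int, m_var, m_load.

Problem sizes: each replication uses the full study panel (30 persons x 100
occasions, m = 5 imputations, 30 iterations).  The replication counts in
the shipped test-suite are scaled to desk scale as this package's own
defaults for continuous verification: H = 6 for the MI-method checks, H =
30 for the list-wise-deletion check (cheap, and its RMSE is bias-dominated
so it stabilises quickly), H = 20 complete-data fits for the CI-coverage
validity check.  The `StudyConfig` presets smoke/scaled/paper (H = 2 / 50 /
500) expose the larger designs through the CLI.

## What the generator does and does not emulate

The synthetic panels reproduce the generating process of the simulation
design: stationary initial conditions (the bundled presets draw
eta[i,1] from the stationary distribution implied by the dynamics and the
covariate moments), i.i.d. Bernoulli(0.5) and standard-normal covariates,
uniform auxiliaries, and the two logistic missingness mechanisms at ~30%.
Real intensive longitudinal data differ in ways the generator deliberately
ignores: unequal spacing, person-specific baselines and dynamics (random
effects), correlated measurement errors, non-Gaussian and bounded item
scales, and drop-out-style monotone missingness.  Passing tests therefore
certify the machinery and the comparative behaviour of the handling
methods under the stated conditions, not performance on any particular
empirical data set.

## Known limitations and observed behaviour

* **Factor-score self-reference.**  On occasions where an indicator block
  is observed, the smoothed factor score is close to a deterministic linear
  combination of that block (an R² near 1 when regressing an indicator on
  its siblings and its factor's score).  The univariate imputation models
  are fitted on exactly those occasions but *applied* on occasions where
  the score was computed without the block.  Under block-wise (NMAR)
  missingness this misapplied conditional weakens the within-block
  coherence of MI-FS imputations; the subsequent model fit absorbs the
  incoherence into the measurement-error variances (inflated, with
  coverage far below nominal) while loadings remain nearly unbiased, and it
  underestimates the process-noise variances.  This is a property of the
  MI-FS construction itself, not of a particular engine; where the damage
  lands (error variances vs. loadings) can differ between engines.
* **NMAR truncation.**  PMM imputes only observed donor values; when
  missingness selects extreme latent values, the imputed distribution is
  truncated relative to the truth.  MI-FS mitigates but does not remove
  the resulting bias in intercepts and variance parameters — visible in
  the below-nominal coverage the tests assert.
* **List-wise deletion under high autocorrelation** loses about half the
  rows (two covariates at 30% each) and distorts time dependencies; its
  measurement-intercept group RMSE is bias-dominated and sits around 2 in
  our runs — large relative to the ≈1 of the MI methods, but the "2" itself
  is a boundary value, sensitive to the replication draw at small H.
* The optimizer's finite-difference gradients limit reproducible optimum
  location to roughly 1e-5; identities asserted at 1e-8 therefore compare
  runs that share the same deterministic optimization path.
* Multilevel extensions (random intercepts), correlated measurement
  errors, categorical targets beyond binary, and model-compatible
  (Bartlett-style) imputation are out of scope.
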