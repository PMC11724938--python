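# mifs — multiple imputation with longitudinal factor scores

Intensive longitudinal studies (for instance ecological momentary
assessments of affect) measure latent constructs through multi-item scales,
over many occasions per person.  When the *latent factor itself* drives
nonresponse — a highly stressed participant skips the whole stress scale —
all indicators of that factor go missing simultaneously, a nonignorable
(NMAR) pattern that ordinary missing-data tools handle poorly: the items
that carry the most information about the missing values are missing too.

`mifs` implements a missing-data strategy for this setting: **multiple
imputation with factor scores (MI-FS)**.  Longitudinal factor scores are
estimated from the incomplete panel with a state-space process factor
analysis (PFA) model, and then injected — together with lagged variables
and missingness indicators — into a chained-equations (MICE-style)
imputation model.  The package contains everything needed to study the
approach end to end:

* a linear Gaussian state-space / PFA core: simulation, Kalman filtering,
  fixed-interval smoothing, and maximum likelihood by the prediction-error
  decomposition (`ProcessFactorModel` / `PFAResults`);
* NMAR and MAR missingness generators with logistic mechanisms and
  rate-calibrated intercepts;
* a chained-equations engine with predictive mean matching and logistic
  draws, plus convergence diagnostics (potential scale reduction);
* four handling pipelines — list-wise deletion (LD), MI on manifest
  variables (MI-MV), partial MI (PMI-MV, covariates imputed / dependent
  variables by FIML), and MI-FS — pooled by the standard combining rules;
* a Monte Carlo harness computing bias, relative bias, SE, MCSE, RMSE,
  dSEfull, power and coverage over replicated conditions.

## The model

The core model, written in the field's standard notation, is

    eta_it = alpha + F eta_{i,t-1} + B x_it + zeta_it,   zeta_it ~ N(0, S_zeta)
    y_it   = tau + Lambda eta_it + A x_it + eps_it,      eps_it ~ N(0, S_eps)

with latent VAR(1) factors eta (auto-/cross-regressions in F, covariate
effects B), manifest indicators y loading on the factors through Lambda
(one loading per factor fixed at 1), and diagonal measurement noise.
Missing y cells cost nothing beyond skipping their rows in the filter
(full-information ML); smoothed factor scores E[eta_it | all of person i's
observed data] come from the fixed-interval smoother.

## A worked example

```python
import numpy as np
from mifs import (pfa_preset, pfa_template, simulate_panel,
                  factor_dependent_spec, calibrate_phi0,
                  apply_factor_dependent, fit_ml, run_ld, run_mi_fs,
                  ImputationSpec)

gen = pfa_preset("low")                       # true generating model (a1 = a2 = 0.5)
ref_panel, ref_latent = simulate_panel(gen, 200, 200, seed=11)
mspec = calibrate_phi0(ref_panel, factor_dependent_spec(), latent=ref_latent)

panel, latent = simulate_panel(gen, 30, 100, seed=7)          # complete data
masked = apply_factor_dependent(panel, latent, mspec, seed=8)  # ~30% NMAR

template = pfa_template("low")                # analysis model (free parameters)
ld = run_ld(masked, template)                 # list-wise deletion + FIML
mifs_ = run_mi_fs(masked, template, ImputationSpec(m=5, n_iter=30, seed=9),
                  pfa_template("low", covariates=False))

print("max rhat:", round(mifs_.imputations.max_rhat(), 3))
keep = ["a1", "a2", "b1", "b2"]
print(ld.summary().loc[keep][["estimate", "se"]].round(3))
print(mifs_.table.loc[keep][["estimate", "se"]].round(3))
```

Output:

```
max rhat: 1.038
    estimate     se
a1     0.402  0.026
a2     0.321  0.029
b1    -0.165  0.019
b2    -0.230  0.041
           estimate     se
parameter
a1            0.584  0.014
a2            0.476  0.019
b1           -0.219  0.015
b2           -0.225  0.025
```

Reading it: the chained-equations chains mix (potential scale reduction
1.04, below the usual 1.1 bar).  List-wise deletion drops the roughly half
of occasions with a missing covariate and treats the survivors as
consecutive, which visibly attenuates the autoregressive parameters (0.40
and 0.32 against a truth of 0.5); MI-FS, informed by the factor scores,
recovers them (0.58 and 0.48) with smaller standard errors.  The
cross-regressions (truth −0.2, −0.3) come out at −0.22 and −0.23 here —
closer under MI-FS for b1, attenuated under both for b2 on this single
replication.

The same machinery scales to full study conditions through the harness:

```python
from mifs.evaluation import StudyConfig, run_condition
perf = run_condition(StudyConfig(autocorr="low", mechanism="factor_dependent",
                                 methods=("LD", "MI-FS"), H=50, master_seed=1))
print(perf.by_group())
```

A thin CLI mirrors the library (`mifs simulate | mask | impute | fit |
study`); run `mifs --help`.

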