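# penmpr — penalized variable selection for Weibull multi-parameter regression

`penmpr` fits parametric survival models in which covariates act on **both**
the scale and the shape of the Weibull hazard,

```
h(t) = tau * gamma * t^(gamma - 1),    log tau = x'beta,   log gamma = z'alpha,
```

and selects which covariates matter in each component by penalized maximum
likelihood.  It is aimed at biostatisticians analysing right-censored
time-to-event data who suspect non-proportional hazards: a covariate in the
shape component changes how the hazard evolves over time, so the usual
single-component (proportional-hazards-style) selection is not enough.
When all shape slopes are zero the model collapses to a parametric PH model
and `exp(beta_k)` is the ordinary hazard ratio; in general the ratio for a
one-unit increment of a shared covariate is time-dependent,

```
HR(t) = exp(beta_k + alpha_k) * t^( exp(z'alpha) * (exp(alpha_k) - 1) ).
```

## What it does

- **Penalties.** LASSO, SCAD (`a = 3.7`) and adaptive LASSO, with either one
  tuning parameter shared by both components or a separate
  `(lambda_beta, lambda_alpha)` pair — the two components live on different
  scales, so separate penalties are often worth the extra tuning dimension.
  Intercepts are never penalized; covariates are standardized internally and
  results are reported on the original scale.
- **Estimation.** The penalized log-likelihood
  `l0(theta) - n * sum_j J_lambda(|theta_j|)` is made twice differentiable by
  the smooth surrogate `a(x) = sqrt(x^2 + eps^2) - eps` (`eps = 1e-4`) and
  maximized by a safeguarded Newton-Raphson on the analytic score and block
  information matrix.  Standard errors use the sandwich covariance
  `I^-1 I0 I^-1`.
- **Tuning.** `BIC(lambda) = -2 l0(theta_hat) + df log n` with effective
  degrees of freedom `df = tr[I^-1 I0]`, minimized by a seeded differential
  evolution search (the BIC surface is multi-modal in lambda); a grid search
  is available as a baseline and for surface diagnostics.
- **Simulation engine.** A generator and replicated-study runner for the
  validation design (AR(1)-correlated standard-normal covariates, sparse
  truth, uniform censoring calibrated to a target proportion) reporting
  selection metrics (C, IC, PT, MSE) and inference metrics (bias, SE, SEE,
  coverage).

See `docs/methods.md` for the model, the algorithm, and every numerical
choice.

## Worked example

Simulate one dataset from the built-in study design (n = 500, 10 correlated
covariates, truth `beta = (-1.5, -1, 0, 0, 0, 0, 0, -0.8, 0.5, 0, 0)`,
`alpha = (0.5, 0.4, 0, 0, 0, 0.4, -0.2, 0, 0, 0, 0)`, 25% censoring) and run
the full adaptive-LASSO pipeline with separate tuning parameters:

```python
import numpy as np
from penmpr import (SimulationScenario, generate_dataset, fit_unpenalized,
                    PenaltyConfig, select_lambda_de)

scenario = SimulationScenario(n=500, seed=7)
data = generate_dataset(scenario, replicate_seed=7)

unpen = fit_unpenalized(data)                       # init + adaptive weights
config = PenaltyConfig(family="alasso", structure="separate")
result = select_lambda_de(data, config, seed=7, unpenalized=unpen)
fit = result.best_fit

print("lambda* =", np.round(result.lambda_star, 4),
      " BIC =", round(result.bic_star, 1),
      " effective df =", round(fit.effective_df, 2))
```

```
lambda* = [0.0057 0.0065]  BIC = 1087.4  effective df = 9.06
```

The selected model (de-selected slopes reported as 0, sandwich SEs in
parentheses):

```
scale:  -1.49(0.09) -0.89(0.08) 0 0 0 -0.12(0.08) 0 -0.85(0.07) +0.52(0.06) 0 0
shape:  +0.50(0.04) +0.35(0.03) 0 0 0 +0.40(0.04) -0.16(0.03) 0 0 0 0
```

The shape support `{x1, x5, x6}` is recovered exactly and the scale support
`{x1, x7, x8}` is recovered up to one extra small coefficient (`x5`,
-0.12 +- 0.08) — at n = 500 an occasional false inclusion is expected; the
replicated studies quantify how often.  The effective df of 9.06 counts the
nine retained slopes-plus-intercepts worth of model complexity, against
22 parameters in the unpenalized fit.  Because `x1` keeps a shape
coefficient (+0.35), its hazard ratio is time-dependent; for a covariate
with no shape effect the ratio would be the constant `exp(beta_k)` — e.g. a
scale-only coefficient of -0.98 means hazard ratio
`exp(-0.98) = 0.375`, a 62.5% risk reduction per unit.

### Command line

The same pipelines are exposed as a CLI driven by a single YAML file naming
the input table (CSV/TSV), the column roles, the penalty and the tuning
settings:

```sh
penmpr fit      config.yaml    # coefficient table + fit summary
penmpr simulate config.yaml    # replicated study -> metric tables
penmpr diagnose config.yaml    # Weibull adequacy points + BIC surface
```

`fit` writes `coefficients.csv` (estimate, SE, active flag, 5% Wald
significance), `fit_summary.yaml` (lambda*, df, l0, BIC) and the fully
resolved configuration for reproducibility.  `diagnose` writes the
Kaplan-Meier based `(log t, log H(t))` points whose straight-line shape
(slope gamma) supports a Weibull baseline.  Exit codes: 0 success, 2
configuration error, 3 convergence failure.

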