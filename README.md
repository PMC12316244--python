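# robcens

Bayesian robust symmetric regression for censored continuous outcomes.

Medical and epidemiological outcomes — survival times, lengths of stay,
biomarker levels — are routinely both *heavy-tailed* (a few extreme
patients dominate least-squares fits) and *censored* (follow-up ends before
the event).  `robcens` fits the linear model

    y*_i = x_i' β + ε_i,   ε_i ~ Student-t(0, σ², ν)  |  Cauchy(0, σ)  |  N(0, σ²)

where y*_i is latent and only

    y_i = y*_i  (observed),   y_i = L_i  (left-censored, y*_i ≤ L_i),
    y_i = U_i   (right-censored, y*_i ≥ U_i)

is recorded.  The likelihood handles censoring exactly — density f for
observed rows, F(L_i) for left-censored, 1 − F(U_i) for right-censored —
with no imputation at the likelihood level.  Priors are β ~ N(0, τ²I)
(τ² = 10⁴), σ ~ Half-Cauchy(0, 5), and ν ~ Gamma(2, 0.1) truncated to
ν > 2 (ν is fixed at 1 for the Cauchy model and absent for the Normal
benchmark).

Inference is a Gibbs sampler with double data augmentation — truncated-normal
imputation of censored latents and the Gamma scale-mixture representation of
the t — plus a collapsed Metropolis move for (σ, ν).  The package also
ships:

* rank-normalized split-R̂ and bulk/tail ESS diagnostics with
  brms-style summary tables (Estimate, Est_Error, CI_Lower, CI_Upper,
  R̂, Bulk_ESS, Tail_ESS);
* model comparison by LPD, WAIC, and PSIS-LOO/LOOIC with Pareto-k
  diagnostics, plus posterior predictive checks;
* a simulation harness measuring bias, RMSE, empirical 95% coverage, and
  credible-interval width under 0/10/20/40% right-censoring;
* CSV I/O for censored datasets and an adapter for the public NCCTG
  lung-cancer layout (`time`, `status`, `age`, `sex`, `ph.ecog`).

See `docs/methods.md` for the model, sampler, and design details.

## Worked example

Simulate the benchmark design (β = (1, 2, −1), σ = 1, t₃ errors, n = 300,
10% right-censoring) and fit the Student-t model:

```python
from robcens import (ErrorFamily, SamplerConfig, SimulationConfig,
                     generate_dataset, run_mcmc, summarize)

data, truth = generate_dataset(SimulationConfig(censor_rate=0.1), seed=1)
fit = run_mcmc(data, ErrorFamily.student_t(),
               cfg=SamplerConfig(chains=2, iterations=2000, warmup=1000, seed=3))
print(summarize(fit).round(3))
```

```
             Estimate  Est_Error  CI_Lower  CI_Upper   Rhat  Bulk_ESS  Tail_ESS
Parameter
b_Intercept     0.918      0.116     0.692     1.143  1.001  1147.298  1609.117
b_x1            1.953      0.150     1.659     2.241  0.999  1165.161  1625.526
b_x2           -0.837      0.171    -1.171    -0.489  0.999  1057.674  1247.203
sigma           1.250      0.098     1.068     1.455  1.019    75.020   189.923
nu              4.536      1.589     2.665     9.318  1.033    39.043    54.335
```

All three 95% credible intervals cover the generating coefficients, and
the degrees-of-freedom posterior puts most of its mass near the generating
ν = 3 (the ν–σ pair is weakly identified at n = 300, so both intervals are
wide).  Comparing error families on the same data:

```python
from robcens import compare_models
report = compare_models(data, [ErrorFamily.student_t(), ErrorFamily.cauchy(),
                               ErrorFamily.normal()],
                        cfg=SamplerConfig(chains=2, iterations=800, warmup=400, seed=5))
print(report.table.round(2))
```

```
              LPD     WAIC  pWAIC  elpd_LOO  pLOO    LOOIC  n_pareto_k_gt_0.7
Model
student_t -532.04  1072.98   4.45   -536.52  4.48  1073.05                  0
cauchy    -550.27  1110.02   4.74   -555.04  4.76  1110.07                  0
normal    -543.49  1096.16   4.59   -548.12  4.63  1096.23                  0
```

The Student-t model attains the smallest WAIC and LOOIC on heavy-tailed
censored data, as it should when the truth is t₃.

The same workflows are available from the shell:

```bash
robcens simulate -R 200 --censor-rate 0.1 --seed 1 --out-dir sim-out
robcens fit data.csv --response y --status-col status --covariates x1,x2 \
        --family student_t --out-dir fit-out
robcens compare data.csv --response y --status-col status --covariates x1,x2 \
        --out-dir cmp-out
```

Every run writes a `manifest.json` sufficient to reproduce it bit-identically.

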