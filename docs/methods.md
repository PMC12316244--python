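# Methods

## Model

`robcens` fits the latent linear model

    y*_i = x_i' beta + eps_i,        i = 1..n,

where the error is symmetric around zero with scale sigma and one of three
families: Student-t with nu degrees of freedom, Cauchy (identically
Student-t with nu = 1), or Normal (the nu -> infinity benchmark).  The
response is observed only inside a per-observation interval (L_i, U_i):

    y_i = y*_i          if L_i < y*_i < U_i        (observed)
    y_i = L_i           if y*_i <= L_i             (left-censored)
    y_i = U_i           if y*_i >= U_i             (right-censored)

and the likelihood is exact in the censoring: observed rows contribute the
density f(y_i | x_i'beta, sigma, nu), left-censored rows the CDF
F(L_i | ...), right-censored rows the survival 1 - F(U_i | ...).  The full
likelihood is the product over rows.  Survival terms are always evaluated
through the log-survival function of the family (regularized incomplete
beta for t, arctangent tail for Cauchy, `log_ndtr` for the normal), never
as `1 - exp(logcdf)`: under 40% right-censoring many F(U_i) sit close
enough to 1 that the naive difference cancels catastrophically.

Priors (defaults, overridable in `PriorConfig`):

| parameter | prior                       | default        | role |
|-----------|-----------------------------|----------------|------|
| beta      | N(0, tau^2 I)               | tau^2 = 10^4   | effectively flat on the response scale |
| sigma     | Half-Cauchy(0, A)           | A = 5          | weakly informative scale prior |
| nu        | Gamma(shape, rate), nu > 2  | shape 2, rate 0.1 | keeps error variance finite; Cauchy fixes nu = 1 outside this support by construction |

Two additional named presets (`lung`, `gaussian-benchmark`) carry the
tighter weakly informative blocks used in applied re-analyses
(N(0, 5^2) coefficients, Half-Cauchy(0, 2) scale); nothing is hard-coded to
one prior block.

## Posterior simulation

The sampler is Gibbs with double data augmentation rather than HMC/NUTS:
every conditional is then an exact textbook draw and unit-testable in
isolation.

1. **Censored latents.** Given (beta, sigma, lambda), each right-censored
   y*_i is drawn from N(x_i'beta, sigma^2/lambda_i) truncated to
   [U_i, inf) (left-censored mirrored).  Sampling is inverse-CDF on the
   tail mass; when that mass underflows double precision (standardized
   bound beyond ~37) an exponential-proposal rejection sampler takes over,
   so deep censoring never produces NaN.
2. **Mixing scales.** A t error is a scale mixture of normals:
   eps_i | lambda_i ~ N(0, sigma^2/lambda_i), lambda_i ~ Gamma(nu/2, nu/2).
   The conditional is Gamma((nu+1)/2, (nu + eps_i^2/sigma^2)/2).  The
   Normal family freezes lambda at 1; the Cauchy family uses nu = 1.
3. **Coefficients.** Conjugate multivariate normal with precision
   X' Lambda X / sigma^2 + I/tau^2.
4. **Scale.** The half-Cauchy prior is expanded as
   sigma^2 | a ~ InvGamma(1/2, 1/a), a ~ InvGamma(1/2, 1/A^2), giving
   conjugate inverse-gamma draws for sigma^2 and a.
5. **Degrees of freedom.** Random-walk Metropolis on eta = log(nu - 2)
   against the product of Gamma(lambda_i; nu/2, nu/2) terms and the
   truncated-Gamma prior (truncation constant cancels; Jacobian included).
   The step adapts toward 0.44 acceptance during warmup and is frozen
   afterwards, preserving detailed balance post-warmup.

### The collapsed (sigma, nu) move

The pure conditional sweep mixes sigma and nu only through lambda, and the
three are strongly coupled: measured integrated autocorrelation times were
in the hundreds (ESS ~ 4 out of 2000 draws).  Each sweep therefore ends
with a joint random-walk Metropolis move on (log sigma, log(nu - 2))
targeting p(sigma, nu | beta, y*) with **lambda and a integrated out** —
the latent residuals are Student-t once lambda is marginalized, and the
sigma prior is half-Cauchy once a is marginalized.  Immediately after the
move both lambda and a are redrawn from their full conditionals, making the
composite a valid partially-collapsed Gibbs step (marginal-then-conditional
draw).  Refreshing a is not optional: leaving it stale breaks invariance,
which the joint-distribution test below detects within seconds.  With the
move, sigma/nu bulk ESS rises from ~4 to ~40-300 per 1000 kept draws;
coefficient ESS is 1000+.

Initialization is cheap and in-support: beta by least squares on the
uncensored rows (zeros if fewer than p+1), sigma = 1.4826 x MAD of those
residuals (1 if degenerate), lambda = 1, nu = 4, censored latents at their
bound +/- 0.5 sigma.  Chains get independent `SeedSequence`-spawned
streams; identical inputs give bit-identical draws.

### Correctness testing

Beyond per-conditional oracles (grid posteriors, closed-form conjugacy,
KS against the half-Cauchy CDF), the suite runs a successive-conditional
joint-distribution test: alternately simulating data from the model given
the current parameters and applying one full sweep must leave the prior
distribution of (beta, sigma, nu) exactly invariant, checked by KS tests
against the closed-form prior marginals (alpha = 0.01,
Bonferroni-corrected).  The test chain uses n = 6 rows with both censoring
directions active: fewer rows weaken the data's anchoring of successive
states and so decorrelate the chain, which keeps the KS tests honest at
moderate thinning.

## Diagnostics

Split-R-hat and bulk ESS follow the modern rank-normalized definitions:
chains are split in half, draws are mapped to normal scores through their
average ranks, and ESS truncates the autocorrelation sum by Geyer's initial
monotone positive-sequence rule.  Tail ESS is the minimum ESS of the 5%-
and 95%-quantile exceedance indicators.  The implementations agree with
arviz within 2% on shared fixtures (cross-checked in the test suite; arviz
is not a runtime dependency).  Summary tables report posterior mean,
posterior SD, and equal-tailed 2.5%/97.5% quantiles under the column names
Estimate / Est_Error / CI_Lower / CI_Upper / Rhat / Bulk_ESS / Tail_ESS.

## Model comparison

All criteria consume the pointwise log-likelihood matrix of the
observed-data censored likelihood (never the augmented one):

* lppd via log-sum-exp over draws;
* WAIC = -2(lppd - pWAIC), pWAIC the summed posterior variance of
  pointwise log-likelihoods;
* PSIS-LOO with tail fraction M = min(0.2 S, 3 sqrt(S)), generalized-Pareto
  tail fit by the Zhang-Stephens profile-posterior-mean method with the
  usual weak regularization of the shape toward 1/2 (scale computed from
  the unregularized shape, matching the reference implementation), smoothed
  weights truncated at the largest smoothed value, and per-observation
  Pareto-k flags at 0.7.  pLOO is defined as lppd - elpd_LOO; LOOIC =
  -2 elpd_LOO.

PSIS-LOO is verified against exact leave-one-out refits on a conjugate
fixture (agreement within 0.1 total elpd) and against arviz on a fitted
model.

## Synthetic-data generator and simulation harness

The generator emulates the benchmark design: x1 ~ Uniform(-1, 1),
x2 ~ Bernoulli(0.5), beta = (1, 2, -1), sigma = 1, n = 300, errors
Student-t (nu = 3 unless stated) or Cauchy.  Right censoring is type-I at
a threshold c chosen as the empirical (1 - rate) quantile of the
replicate's latent responses, so a nominal 10/20/40% rate censors exactly
ceil(n x rate) rows; c is recorded as the upper bound of *every* row, since
the mechanism applies to all units — this is what makes posterior
predictive censoring fractions comparable to the data's.  The harness
reports per-parameter Bias, RMSE, empirical 95% coverage, and mean
credible-interval width across replicates, with per-replicate seeds derived
from the master seed via `SeedSequence` so any replicate is independently
reproducible.  Replicate failures are tolerated up to 1% and excluded with
a warning; beyond that the run aborts as systematically broken.

What the generator does not emulate: covariate-dependent or random
censoring times, skewed errors, heteroscedasticity, and model
misspecification beyond the wrong symmetric family.  Passing tests
therefore speak to the estimator's behavior under the stated design, not
to robustness against those violations.

Default problem sizes in the shipped tests and acceptance script are
R = 200 replications per design cell with 2 chains per fit (the full-scale
study used for the tables is R = 1000 with longer chains; R = 200 leaves
coverage estimates with binomial SE of ~0.015, which the tolerance bands
account for).

## Numerical choices and edge cases

* Infinite bounds are +/-inf sentinels, never NaN; likelihood dispatch is
  purely on the status code.
* Interval-censored rows are representable in the data model but not
  supported by the sampler in this version.
* Datasets with every row censored on one side run with a warning (the
  posterior is then prior-dominated).
* Constant or single-draw chains give NaN diagnostics with a warning
  rather than an error.
* A degenerate all-equal PSIS tail sample leaves that observation's
  weights unsmoothed and flags k = NaN.
* The free-nu prior is supported on nu > 2 (finite error variance);
  values in (0, 2] are reachable only as fixed nu (the Cauchy's nu = 1),
  which mirrors the benchmark setup.

## Known limitations

* The Cauchy fit on strongly Cauchy-contaminated data can show Pareto-k
  flags for a handful of extreme observations; the comparison table still
  reports those models but flags the count.
* WAIC/LOOIC orderings between *misspecified* families (e.g. Cauchy vs
  Normal on t3 data) have population-level gaps of the same order as
  single-dataset sampling noise (~15 elpd at n = 300), so a single-seed
  ordering between those two can flip; orderings against the
  correctly specified family are stable.
* No HMC/NUTS backend and no within-chain parallelism; chains are
  independent by seed stream only.
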