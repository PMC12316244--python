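"""Successive-conditional (joint-distribution) test harness for the sampler.

The chain alternates (1) simulating a dataset from the model given the
current parameters — including the latent mixing scales and responses —
and (2) applying one full Gibbs sweep given that dataset.  If every
conditional update is correct, the marginal distribution of the parameters
along this chain is exactly the prior, which is checked by KS tests
against the closed-form prior marginals.
"""

import numpy as np
from scipy import stats

from robcens.censdata import CensoredDataset, CensStatus
from robcens.sampler import AugmentedState, NU_MIN, PriorConfig, gibbs_sweep
from robcens.symlik import ErrorFamily


def draw_prior(prior: PriorConfig, p: int, rng, nu_free: bool = True):
    """One exact draw of (beta, sigma, a, nu) from the prior block."""
    beta = rng.normal(scale=prior.beta_scale, size=p)
    a = (1.0 / prior.sigma_scale**2) / rng.gamma(0.5)  # a ~ InvGamma(1/2, 1/A^2)
    sigma = np.sqrt((1.0 / a) / rng.gamma(0.5))  # sigma^2 | a ~ InvGamma(1/2, 1/a)
    nu = None
    if nu_free:
        while True:  # truncated Gamma(shape, rate) on nu > 2
            nu = rng.gamma(prior.nu_shape, 1.0 / prior.nu_rate)
            if nu > NU_MIN:
                break
    return beta, float(sigma), float(a), nu


def run_geweke_chain(cycles: int = 40_000, thin: int = 10, seed: int = 2024,
                     n: int = 6, prior: PriorConfig | None = None):
    """Run the alternating chain; returns thinned (beta0, beta1, sigma, nu)."""
    prior = prior or PriorConfig(beta_scale=1.2, sigma_scale=1.0,
                                 nu_shape=3.0, nu_rate=0.5)
    rng = np.random.default_rng(seed)
    fam = ErrorFamily.student_t()  # free nu
    X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n)])
    U = np.full(n, np.inf)
    L = np.full(n, -np.inf)
    third = n // 3
    U[:third] = 0.7        # right-censoring active on the first third
    L[third:2 * third] = -0.7  # left-censoring on the second third
    beta, sigma, a, nu = draw_prior(prior, 2, rng)
    out = []
    for cycle in range(cycles):
        # --- data step: simulate everything the model generates given theta
        lam = rng.gamma(nu / 2.0, 2.0 / nu, size=n)
        ystar = X @ beta + sigma / np.sqrt(lam) * rng.standard_normal(n)
        status = np.full(n, int(CensStatus.OBSERVED))
        y = ystar.copy()
        right = ystar >= U
        left = ystar <= L
        status[right] = int(CensStatus.RIGHT)
        y[right] = U[right]
        status[left] = int(CensStatus.LEFT)
        y[left] = L[left]
        data = CensoredDataset(y=y, status=status, lower=L, upper=U, X=X,
                               names=["Intercept", "x1"])
        # --- parameter step: one sweep of the sampler
        state = AugmentedState(beta=beta, sigma=sigma, nu=nu, lam=lam,
                               ystar=ystar, a_aux=a)
        state, _ = gibbs_sweep(state, data, fam, prior, rng, nu_step=0.8,
                               marg_step=0.5)
        beta, sigma, nu, a = state.beta, state.sigma, state.nu, state.a_aux
        if cycle % thin == thin - 1:
            out.append((beta[0], beta[1], sigma, nu))
    arr = np.asarray(out)
    return {"beta0": arr[:, 0], "beta1": arr[:, 1], "sigma": arr[:, 2],
            "nu": arr[:, 3]}, prior


def prior_marginal_cdfs(prior: PriorConfig):
    """Closed-form prior CDFs for the KS comparisons."""
    norm = stats.norm(scale=prior.beta_scale)
    gam = stats.gamma(prior.nu_shape, scale=1.0 / prior.nu_rate)
    tail = gam.sf(NU_MIN)

    def nu_cdf(v):
        return np.clip((gam.cdf(v) - gam.cdf(NU_MIN)) / tail, 0.0, 1.0)

    return {
        "beta0": norm.cdf,
        "beta1": norm.cdf,
        "sigma": lambda s: 2.0 * np.arctan(np.asarray(s) / prior.sigma_scale) / np.pi,
        "nu": nu_cdf,
    }
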