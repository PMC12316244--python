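import numpy as np
import pytest
from scipy import integrate, stats

from robcens.censdata import CensoredDataset, CensStatus
from robcens.diagnostics import summarize
from robcens.sampler import (
    AugmentedState, PriorConfig, SamplerConfig, gibbs_sweep, impute_censored,
    log_prior, run_mcmc, update_beta, update_lambda, update_nu, update_sigma,
    update_sigma_nu_marginal,
)
from robcens.symlik import ErrorFamily
from conftest import make_state


# ---------------------------------------------------------------- log_prior

def test_log_prior_beta_term_at_mode():
    prior = PriorConfig(beta_scale=100.0)
    fam = ErrorFamily.cauchy()
    p = 3
    lp = log_prior(np.zeros(p), prior.sigma_scale, None, prior, fam)
    beta_term = p * (-0.5 * np.log(2 * np.pi * 1e4))
    # at sigma = A the half-Cauchy density is 2/(pi*A*2) = 1/(pi*A)
    sigma_term = np.log(1.0 / (np.pi * prior.sigma_scale))
    assert np.isclose(lp, beta_term + sigma_term)


def test_log_prior_free_nu_below_support_is_minus_inf():
    prior = PriorConfig()
    assert log_prior(np.zeros(2), 1.0, 1.5, prior, ErrorFamily.student_t()) == -np.inf
    assert np.isfinite(log_prior(np.zeros(2), 1.0, 3.0, prior, ErrorFamily.student_t()))


def test_log_prior_rejects_nonpositive_sigma():
    assert log_prior(np.zeros(1), -1.0, 3.0, PriorConfig(), ErrorFamily.normal()) == -np.inf


# ------------------------------------------------------------ update_lambda

def test_lambda_conditional_is_conjugate_gamma(uncensored_dataset, rng):
    """eps = 0, nu = 3 gives Gamma(2, rate 3/2): mean 4/3, var 8/9."""
    data = uncensored_dataset
    beta = np.array([1.0, 2.0])
    state = make_state(data, beta, sigma=1.0, nu=3.0, ystar=data.X @ beta)
    draws = np.array([update_lambda(state, data, ErrorFamily.student_t(), rng)
                      for _ in range(2000)]).ravel()
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - 4.0 / 3.0) < 4 * se
    assert abs(draws.var(ddof=1) - 8.0 / 9.0) < 0.02


def test_lambda_degenerates_to_one_for_large_nu(uncensored_dataset, rng):
    data = uncensored_dataset
    beta = np.array([1.0, 2.0])
    state = make_state(data, beta, nu=1e6, ystar=data.X @ beta)
    lam = np.concatenate([update_lambda(state, data, ErrorFamily.student_t(), rng)
                          for _ in range(50)])
    assert abs(lam.mean() - 1.0) < 0.001


def test_lambda_frozen_at_one_for_normal_family(uncensored_dataset, rng):
    state = make_state(uncensored_dataset, [1.0, 2.0])
    lam = update_lambda(state, uncensored_dataset, ErrorFamily.normal(), rng)
    np.testing.assert_array_equal(lam, 1.0)


def test_gibbs_hierarchy_reproduces_t_residuals(rng):
    """Marginalizing lambda out of the two-stage draw gives t_nu residuals."""
    nu = 3.0
    lam = rng.gamma(nu / 2, 2 / nu, size=20_000)
    eps = rng.standard_normal(20_000) / np.sqrt(lam)
    assert stats.kstest(eps, stats.t(df=nu).cdf).pvalue > 0.01


# ---------------------------------------------------------- impute_censored

def _one_row_right_censored(bound, mu_offset=0.0):
    return CensoredDataset(
        y=np.array([bound]), status=np.array([int(CensStatus.RIGHT)]),
        lower=np.array([-np.inf]), upper=np.array([bound]),
        X=np.array([[1.0]]), names=["Intercept"],
    )


def test_truncation_at_the_mean_gives_half_normal_mean(rng):
    data = _one_row_right_censored(0.0)
    state = make_state(data, [0.0], sigma=1.0)
    draws = np.array([impute_censored(state, data, rng)[0] for _ in range(20_000)])
    # E[Z | Z >= 0] = phi(0)/(1 - Phi(0)) = 0.79788
    assert abs(draws.mean() - np.sqrt(2 / np.pi)) < 0.02
    assert draws.min() >= 0.0


def test_inactive_truncation_recovers_plain_normal(rng):
    data = _one_row_right_censored(-30.0)
    state = make_state(data, [0.0], sigma=1.0)
    draws = np.array([impute_censored(state, data, rng)[0] for _ in range(10_000)])
    assert stats.kstest(draws, stats.norm.cdf).statistic < 0.015


def test_deep_tail_truncation_is_finite_and_respects_bound(rng):
    """Bound 45 sigma above the mean: inverse-CDF mass underflows, the
    exponential-tail fallback must still give finite in-bound draws."""
    data = _one_row_right_censored(45.0)
    state = make_state(data, [0.0], sigma=1.0)
    draws = np.array([impute_censored(state, data, rng)[0] for _ in range(200)])
    assert np.all(np.isfinite(draws)) and np.all(draws >= 45.0)
    assert draws.mean() < 45.2  # tail decays like Exp(45)


def test_left_censoring_mirrors_right(rng):
    data = CensoredDataset(
        y=np.array([0.0]), status=np.array([int(CensStatus.LEFT)]),
        lower=np.array([0.0]), upper=np.array([np.inf]),
        X=np.array([[1.0]]), names=["Intercept"],
    )
    state = make_state(data, [0.0], sigma=1.0)
    draws = np.array([impute_censored(state, data, rng)[0] for _ in range(20_000)])
    assert draws.max() <= 0.0
    assert abs(draws.mean() + np.sqrt(2 / np.pi)) < 0.02


def test_observed_rows_left_untouched(tiny_dataset, rng):
    state = make_state(tiny_dataset, [0.0, 0.0])
    out = impute_censored(state, tiny_dataset, rng)
    obs = tiny_dataset.status == CensStatus.OBSERVED
    np.testing.assert_array_equal(out[obs], tiny_dataset.y[obs])
    assert out[2] >= tiny_dataset.upper[2]
    assert out[3] <= tiny_dataset.lower[3]


# ---------------------------------------------------------------- update_beta

def test_beta_prior_draw_when_no_data(empty_dataset, rng):
    prior = PriorConfig(beta_scale=2.0)
    state = make_state(empty_dataset, [0.0, 0.0])
    draws = np.array([update_beta(state, empty_dataset, prior, rng)
                      for _ in range(4000)])
    assert np.allclose(draws.mean(axis=0), 0.0, atol=0.15)
    assert np.allclose(draws.std(axis=0), 2.0, atol=0.15)


def test_beta_conditional_matches_grid_oracle(rng):
    """Empirical mean/cov of conjugate draws vs a dense-grid posterior."""
    X = np.array([[1.0, -0.8], [1.0, -0.1], [1.0, 0.4], [1.0, 0.9], [1.0, 1.5]])
    ystar = np.array([0.2, 0.9, 1.4, 2.1, 2.8])
    lam = np.array([1.0, 0.5, 2.0, 1.2, 0.8])
    sigma, tau = 0.7, 3.0
    data = CensoredDataset(y=ystar, status=np.zeros(5, dtype=int),
                           lower=np.full(5, -np.inf), upper=np.full(5, np.inf),
                           X=X, names=["Intercept", "x1"])
    prior = PriorConfig(beta_scale=tau)
    state = make_state(data, [0.0, 0.0], sigma=sigma, lam=lam, ystar=ystar)
    # oracle: evaluate the unnormalized conditional on a dense grid
    g = np.linspace(-2, 4, 241)
    B0, B1 = np.meshgrid(g, g, indexing="ij")
    logp = np.zeros_like(B0)
    for i in range(5):
        logp += -0.5 * lam[i] * (ystar[i] - B0 * X[i, 0] - B1 * X[i, 1]) ** 2 / sigma**2
    logp += -0.5 * (B0**2 + B1**2) / tau**2
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean_oracle = np.array([(w * B0).sum(), (w * B1).sum()])
    cov_oracle = np.array([
        [(w * (B0 - mean_oracle[0]) ** 2).sum(), (w * (B0 - mean_oracle[0]) * (B1 - mean_oracle[1])).sum()],
        [(w * (B0 - mean_oracle[0]) * (B1 - mean_oracle[1])).sum(), (w * (B1 - mean_oracle[1]) ** 2).sum()],
    ])
    draws = np.array([update_beta(state, data, prior, rng) for _ in range(8000)])
    np.testing.assert_allclose(draws.mean(axis=0), mean_oracle, atol=0.02)
    np.testing.assert_allclose(np.cov(draws.T), cov_oracle, atol=0.02)


def test_flat_prior_mean_is_weighted_least_squares(uncensored_dataset, rng):
    data = uncensored_dataset
    prior = PriorConfig(beta_scale=1e6)
    state = make_state(data, [0.0, 0.0], sigma=1.0, ystar=data.y)
    draws = np.array([update_beta(state, data, prior, rng) for _ in range(6000)])
    ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    np.testing.assert_allclose(draws.mean(axis=0), ols, atol=0.03)


# --------------------------------------------------------------- update_sigma

def test_sigma_prior_only_marginal_is_half_cauchy(empty_dataset, rng):
    """With no data the (sigma, a) Gibbs pair must leave Half-Cauchy(0, A)
    invariant: KS against the closed-form CDF 2 arctan(sigma/A)/pi."""
    A = 1.5
    prior = PriorConfig(sigma_scale=A)
    state = make_state(empty_dataset, [0.0, 0.0], sigma=1.0, a_aux=1.0)
    keep = []
    for i in range(50_000):
        sigma, a = update_sigma(state, empty_dataset, prior, rng)
        state.sigma, state.a_aux = sigma, a
        if i % 5 == 4:
            keep.append(sigma)
    keep = np.asarray(keep)
    res = stats.kstest(keep, lambda s: 2 * np.arctan(s / A) / np.pi)
    assert res.pvalue > 0.01


def test_sigma_conditional_stochastically_increases_with_rss():
    # InvGamma rate monotonicity, checked on the closed-form conditional
    n, a_aux = 10, 1.0
    for q in (0.5, 1.0, 2.0):
        lo = stats.invgamma(0.5 * (n + 1), scale=1 / a_aux + 0.5 * 4.0).sf(q)
        hi = stats.invgamma(0.5 * (n + 1), scale=1 / a_aux + 0.5 * 8.0).sf(q)
        assert hi > lo


def test_sigma_data_marginal_matches_quadrature(uncensored_dataset, rng):
    """Iterating (sigma, a) with fixed residuals targets the half-Cauchy x
    normal-likelihood posterior; compare to 1-d quadrature."""
    data = uncensored_dataset
    beta = np.array([1.0, 2.0])
    prior = PriorConfig(sigma_scale=2.0)
    state = make_state(data, beta, sigma=1.0, ystar=data.y)
    eps = data.y - data.X @ beta
    keep = []
    for i in range(30_000):
        sigma, a = update_sigma(state, data, prior, rng)
        state.sigma, state.a_aux = sigma, a
        if i % 3 == 2:
            keep.append(sigma)
    keep = np.asarray(keep)

    def unnorm(s):
        return np.exp(-0.5 * np.sum(eps**2) / s**2 - data.n * np.log(s)
                      - np.log1p((s / 2.0) ** 2))

    grid = np.linspace(1e-3, 5, 4000)
    dens = np.array([unnorm(s) for s in grid])
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    res = stats.kstest(keep, lambda s: np.interp(s, grid, cdf))
    assert res.pvalue > 0.01


# ----------------------------------------------------------------- update_nu

def test_nu_identity_proposal_always_accepted(uncensored_dataset, rng):
    state = make_state(uncensored_dataset, [1.0, 2.0], nu=5.0,
                       lam=np.abs(rng.gamma(2, 1, uncensored_dataset.n)))
    nu, accepted = update_nu(state, PriorConfig(), 0.0, rng)
    assert accepted and nu == 5.0


def test_nu_posterior_concentrates_near_truth(rng):
    """lambda ~ Gamma(nu0/2, nu0/2) at n=2000: the MH chain's mean must sit
    within 15% of the 1-d grid-posterior mean."""
    nu0 = 6.0
    n = 2000
    lam = rng.gamma(nu0 / 2, 2 / nu0, size=n)
    data = CensoredDataset(y=np.zeros(n), status=np.zeros(n, dtype=int),
                           lower=np.full(n, -np.inf), upper=np.full(n, np.inf),
                           X=np.ones((n, 1)), names=["Intercept"])
    prior = PriorConfig()
    state = make_state(data, [0.0], nu=4.0, lam=lam)
    chain = []
    for _ in range(4000):
        nu, _ = update_nu(state, prior, 0.25, rng)
        state.nu = nu
        chain.append(nu)
    mh_mean = np.mean(chain[500:])
    # grid oracle over nu > 2
    from scipy.special import gammaln
    grid = np.linspace(2.01, 15, 3000)
    h = grid / 2
    logp = (n * (h * np.log(h) - gammaln(h)) + (h - 1) * np.sum(np.log(lam))
            - h * np.sum(lam) + (prior.nu_shape - 1) * np.log(grid)
            - prior.nu_rate * grid)
    w = np.exp(logp - logp.max())
    w /= w.sum()
    grid_mean = float((w * grid).sum())
    assert abs(mh_mean - grid_mean) / grid_mean < 0.15
    assert abs(grid_mean - nu0) / nu0 < 0.15


def test_collapsed_move_targets_t_marginal(uncensored_dataset, rng):
    """Fixed residuals: iterating the collapsed (sigma) move with nu fixed must
    match the quadrature posterior of sigma under the t likelihood."""
    data = uncensored_dataset
    beta = np.array([1.0, 2.0])
    fam = ErrorFamily.student_t(3.0)
    prior = PriorConfig(sigma_scale=2.0)
    state = make_state(data, beta, sigma=1.0, nu=3.0, ystar=data.y)
    eps = data.y - data.X @ beta
    keep = []
    for i in range(30_000):
        sigma, nu, _ = update_sigma_nu_marginal(state, data, fam, prior, 0.4, 0.0, rng)
        state.sigma = sigma
        if i % 3 == 2:
            keep.append(sigma)
    keep = np.asarray(keep)
    grid = np.linspace(1e-3, 6, 4000)
    logd = np.array([
        np.sum(stats.t.logpdf(eps / s, df=3.0) - np.log(s)) - np.log1p((s / 2.0) ** 2)
        for s in grid
    ])
    dens = np.exp(logd - logd.max())
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    assert stats.kstest(keep, lambda s: np.interp(s, grid, cdf)).pvalue > 0.01


# ------------------------------------------------------------------ run_mcmc

def _sim_data(seed, censor_rate=0.1, n=150, fam=None):
    from robcens.simstudy import SimulationConfig, generate_dataset
    fam = fam or ErrorFamily.student_t(3.0)
    cfg = SimulationConfig(n=n, censor_rate=censor_rate, family_true=fam)
    data, _ = generate_dataset(cfg, seed=seed)
    return data


FAST = SamplerConfig(chains=2, iterations=600, warmup=300, seed=7, compute_loglik=True)


def test_run_mcmc_is_deterministic():
    data = _sim_data(3)
    fam = ErrorFamily.student_t()
    fit1 = run_mcmc(data, fam, cfg=FAST)
    fit2 = run_mcmc(data, fam, cfg=FAST)
    np.testing.assert_array_equal(fit1.beta, fit2.beta)
    np.testing.assert_array_equal(fit1.sigma, fit2.sigma)
    np.testing.assert_array_equal(fit1.nu, fit2.nu)
    np.testing.assert_array_equal(fit1.loglik, fit2.loglik)


def test_cauchy_identical_to_student_t_nu_fixed_one():
    data = _sim_data(5, fam=ErrorFamily.cauchy())
    fit_c = run_mcmc(data, ErrorFamily.cauchy(), cfg=FAST)
    fit_t1 = run_mcmc(data, ErrorFamily.student_t(1.0), cfg=FAST)
    np.testing.assert_array_equal(fit_c.beta, fit_t1.beta)
    np.testing.assert_array_equal(fit_c.sigma, fit_t1.sigma)


def test_normal_family_no_censoring_agrees_with_ols():
    data = _sim_data(11, censor_rate=0.0, n=200, fam=ErrorFamily.normal())
    fit = run_mcmc(data, ErrorFamily.normal(), cfg=FAST)
    summ = summarize(fit)
    ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    for j, name in enumerate(["b_Intercept", "b_x1", "b_x2"]):
        row = summ.loc[name]
        assert abs(row["Estimate"] - ols[j]) < 3 * row["Est_Error"]


def test_no_censoring_makes_imputation_identity(rng):
    data = _sim_data(13, censor_rate=0.0, n=50)
    state = make_state(data, np.zeros(3))
    np.testing.assert_array_equal(impute_censored(state, data, rng), data.y)


def test_exchangeability_under_row_permutation():
    data = _sim_data(17, n=120)
    perm = np.random.default_rng(0).permutation(data.n)
    fit_a = run_mcmc(data, ErrorFamily.student_t(3.0), cfg=FAST)
    fit_b = run_mcmc(data.subset(perm), ErrorFamily.student_t(3.0), cfg=FAST)
    sa, sb = summarize(fit_a), summarize(fit_b)
    # distributional agreement, not same-seed equality
    np.testing.assert_allclose(sa["Estimate"], sb["Estimate"], atol=0.06)
    # loglik columns follow the permutation for fixed parameters
    from robcens.symlik import pointwise_loglik
    beta = np.array([1.0, 2.0, -1.0])
    ll = pointwise_loglik(data, beta, 1.0, ErrorFamily.student_t(3.0))
    ll_perm = pointwise_loglik(data.subset(perm), beta, 1.0, ErrorFamily.student_t(3.0))
    np.testing.assert_allclose(ll_perm, ll[perm])


def test_all_censored_warns_but_runs():
    n = 30
    data = CensoredDataset(y=np.full(n, 2.0), status=np.full(n, 2),
                           lower=np.full(n, -np.inf), upper=np.full(n, 2.0),
                           X=np.ones((n, 1)), names=["Intercept"])
    with pytest.warns(UserWarning, match="censored"):
        fit = run_mcmc(data, ErrorFamily.normal(),
                       cfg=SamplerConfig(chains=1, iterations=200, warmup=100, seed=1))
    assert np.all(np.isfinite(fit.sigma))


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(warmup=2000, iterations=2000)
    with pytest.raises(ValueError):
        SamplerConfig(chains=0)
    with pytest.raises(ValueError):
        PriorConfig(beta_scale=-1.0)
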