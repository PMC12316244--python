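"""Symmetric location-scale error families and the censored log-likelihood.

Three families are supported: Student-t with nu degrees of freedom, Cauchy
(the nu = 1 special case), and Normal (the nu -> inf limit, used as the
benchmark model).  An observation contributes

* ``log f(y_i)``        when fully observed,
* ``log F(L_i)``        when left-censored at L_i,
* ``log (1 - F(U_i))``  when right-censored at U_i,

with location mu_i = x_i' beta and common scale sigma.  The full likelihood
is the product of these per-observation terms.  Right-censored terms go
through the survival function directly (``logsf``), never ``1 - exp(logcdf)``,
so deep censoring in the upper tail does not suffer catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .censdata import CensoredDataset, CensStatus

__all__ = [
    "ErrorFamily",
    "sym_logpdf",
    "sym_logcdf",
    "sym_logsf",
    "pointwise_loglik",
    "loglik_matrix",
    "total_loglik",
]

FAMILIES = ("student_t", "cauchy", "normal")


@dataclass(frozen=True)
class ErrorFamily:
    """Symmetric error family and its degrees of freedom.

    ``nu`` is fixed at 1 for the Cauchy family and ignored for the Normal
    family.  Kernels accept any nu > 0; the restriction nu > 2 applies only
    at the prior level when nu is a free parameter.
    """

    family: str
    nu: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "cauchy":
            if self.nu not in (None, 1, 1.0):
                raise ValueError("cauchy is Student-t with nu fixed at 1")
            object.__setattr__(self, "nu", 1.0)
        elif self.family == "student_t":
            if self.nu is not None and self.nu <= 0:
                raise ValueError("student_t requires nu > 0")
        else:
            object.__setattr__(self, "nu", None)

    @classmethod
    def student_t(cls, nu: float | None = None) -> "ErrorFamily":
        return cls("student_t", nu)

    @classmethod
    def cauchy(cls) -> "ErrorFamily":
        return cls("cauchy", 1.0)

    @classmethod
    def normal(cls) -> "ErrorFamily":
        return cls("normal", None)

    @property
    def nu_free(self) -> bool:
        """True when nu is an unknown parameter to be sampled."""
        return self.family == "student_t" and self.nu is None


def _check_sigma(sigma):
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be strictly positive")


def _standardize(y, mu, sigma):
    _check_sigma(sigma)
    return (np.asarray(y, dtype=float) - mu) / sigma


def _dispatch(fam: ErrorFamily, nu=None):
    """Return (scipy frozen-family callables, effective nu)."""
    if fam.family == "normal":
        return stats.norm, None
    eff_nu = nu if nu is not None else fam.nu
    if eff_nu is None:
        raise ValueError("student_t kernels need nu: fix it in ErrorFamily or pass nu=")
    if np.any(np.asarray(eff_nu) <= 0):
        raise ValueError("nu must be strictly positive")
    return stats.t, eff_nu


def sym_logpdf(y, mu, sigma, fam: ErrorFamily, nu=None):
    """Log density of the location-scale family: log f((y-mu)/sigma) - log sigma."""
    z = _standardize(y, mu, sigma)
    dist, eff_nu = _dispatch(fam, nu)
    if eff_nu is None:
        return dist.logpdf(z) - np.log(sigma)
    return dist.logpdf(z, df=eff_nu) - np.log(sigma)


def sym_logcdf(y, mu, sigma, fam: ErrorFamily, nu=None):
    """Log CDF log F((y-mu)/sigma); the left-censoring contribution."""
    z = _standardize(y, mu, sigma)
    dist, eff_nu = _dispatch(fam, nu)
    return dist.logcdf(z) if eff_nu is None else dist.logcdf(z, df=eff_nu)


def sym_logsf(y, mu, sigma, fam: ErrorFamily, nu=None):
    """Log survival log(1 - F((y-mu)/sigma)) via the stable complementary path."""
    z = _standardize(y, mu, sigma)
    dist, eff_nu = _dispatch(fam, nu)
    return dist.logsf(z) if eff_nu is None else dist.logsf(z, df=eff_nu)


def pointwise_loglik(data: CensoredDataset, beta, sigma, fam: ErrorFamily, nu=None):
    """Per-observation censored log-likelihood contributions at (beta, sigma, nu).

    Element i is log f(y_i) for observed rows, log F(L_i) for left-censored
    rows, and log S(U_i) for right-censored rows, with mu_i = x_i' beta.
    """
    beta = np.asarray(beta, dtype=float)
    mu = data.X @ beta
    if not np.all(np.isfinite(mu)):
        bad = int(np.where(~np.isfinite(mu))[0][0])
        raise FloatingPointError(f"non-finite linear predictor at row {bad}")
    out = np.empty(data.n)
    obs = data.status == CensStatus.OBSERVED
    left = data.status == CensStatus.LEFT
    right = data.status == CensStatus.RIGHT
    if obs.any():
        out[obs] = sym_logpdf(data.y[obs], mu[obs], sigma, fam, nu)
    if left.any():
        out[left] = sym_logcdf(data.lower[left], mu[left], sigma, fam, nu)
    if right.any():
        out[right] = sym_logsf(data.upper[right], mu[right], sigma, fam, nu)
    return out


def loglik_matrix(data: CensoredDataset, beta_draws, sigma_draws, fam: ErrorFamily,
                  nu_draws=None):
    """Pointwise log-likelihood for a stack of posterior draws.

    Parameters are arrays over S draws: ``beta_draws`` (S, p), ``sigma_draws``
    (S,), and ``nu_draws`` (S,) when nu varies by draw.  Returns an (S, n)
    matrix, the input to WAIC and PSIS-LOO.
    """
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    sigma_draws = np.asarray(sigma_draws, dtype=float).reshape(-1, 1)
    mu = beta_draws @ data.X.T  # (S, n)
    if nu_draws is not None:
        nu = np.asarray(nu_draws, dtype=float).reshape(-1, 1)
    else:
        nu = None
    out = np.empty_like(mu)
    obs = data.status == CensStatus.OBSERVED
    left = data.status == CensStatus.LEFT
    right = data.status == CensStatus.RIGHT
    if obs.any():
        out[:, obs] = sym_logpdf(data.y[None, obs], mu[:, obs], sigma_draws, fam, nu)
    if left.any():
        out[:, left] = sym_logcdf(data.lower[None, left], mu[:, left], sigma_draws, fam, nu)
    if right.any():
        out[:, right] = sym_logsf(data.upper[None, right], mu[:, right], sigma_draws, fam, nu)
    return out


def total_loglik(data: CensoredDataset, beta, sigma, fam: ErrorFamily, nu=None) -> float:
    """Full censored log-likelihood: the sum of pointwise contributions."""
    if data.y.shape[0] == 0:
        return 0.0
    return float(np.sum(pointwise_loglik(data, beta, sigma, fam, nu)))
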