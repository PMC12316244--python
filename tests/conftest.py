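import numpy as np
import pytest

from robcens.censdata import CensoredDataset, CensStatus
from robcens.sampler import AugmentedState, PriorConfig
from robcens.symlik import ErrorFamily


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_dataset():
    """n=5, p=2 dataset with one right- and one left-censored row."""
    X = np.array([[1.0, -0.5], [1.0, 0.2], [1.0, 1.1], [1.0, -1.3], [1.0, 0.7]])
    y = np.array([0.4, 1.1, 2.0, -0.9, 1.5])
    status = np.array([0, 0, 2, 1, 0])
    lower = np.array([-np.inf, -np.inf, -np.inf, -0.9, -np.inf])
    upper = np.array([np.inf, np.inf, 2.0, np.inf, np.inf])
    return CensoredDataset(y=y, status=status, lower=lower, upper=upper, X=X,
                           names=["Intercept", "x1"])


@pytest.fixture
def uncensored_dataset(rng):
    """n=40 fully observed regression dataset."""
    n = 40
    X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n)])
    y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)
    status = np.zeros(n, dtype=int)
    return CensoredDataset(y=y, status=status, lower=np.full(n, -np.inf),
                           upper=np.full(n, np.inf), X=X, names=["Intercept", "x1"])


@pytest.fixture
def empty_dataset():
    return CensoredDataset(y=np.empty(0), status=np.empty(0, dtype=int),
                           lower=np.empty(0), upper=np.empty(0),
                           X=np.empty((0, 2)), names=["Intercept", "x1"])


@pytest.fixture
def default_prior():
    return PriorConfig()


def make_state(data, beta, sigma=1.0, nu=4.0, lam=None, ystar=None, a_aux=1.0):
    beta = np.asarray(beta, dtype=float)
    return AugmentedState(
        beta=beta, sigma=sigma, nu=nu,
        lam=np.ones(data.n) if lam is None else np.asarray(lam, float),
        ystar=data.y.copy() if ystar is None else np.asarray(ystar, float),
        a_aux=a_aux,
    )


ALL_FAMILIES = [ErrorFamily.student_t(3.0), ErrorFamily.cauchy(), ErrorFamily.normal()]
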