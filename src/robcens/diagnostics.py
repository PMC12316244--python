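"""MCMC convergence diagnostics and posterior summary tables.

Implements the modern (rank-normalized, split-chain) definitions of the
potential scale reduction factor R-hat and of bulk / tail effective sample
size: chains are split in half, draws are mapped to normal scores through
their ranks, and the ESS autocorrelation sum is truncated by Geyer's
initial monotone positive-sequence rule.  Tail ESS is the smaller of the
ESS of the 5%- and 95%-quantile exceedance indicators.

``summarize`` renders a fit as one row per parameter with posterior mean,
SD, equal-tailed credible bounds, and the three diagnostics — the column
layout used throughout for reporting (Estimate, Est_Error, CI_Lower,
CI_Upper, Rhat, Bulk_ESS, Tail_ESS).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .sampler import FitResult

__all__ = ["split_rhat", "ess_bulk", "ess_tail", "summarize"]


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """Split each chain in half along the draw axis; drops an odd last draw."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = draws.shape
    half = n // 2
    return np.vstack([draws[:, :half], draws[:, half:2 * half]])


def _z_scale(draws: np.ndarray) -> np.ndarray:
    """Rank-normalize jointly across all chains (average ranks, normal scores)."""
    shape = draws.shape
    r = rankdata(draws, method="average").reshape(shape)
    return ndtri((r - 0.375) / (draws.size + 0.25))


def _check(draws: np.ndarray) -> bool:
    """False when the diagnostics are undefined (too short or constant)."""
    if draws.shape[1] < 4:
        return False
    if np.allclose(draws, draws.flat[0]):
        return False
    return True


def split_rhat(draws) -> float:
    """Rank-normalized split potential scale reduction factor.

    ``draws`` is a (chains, iterations) array for one scalar parameter; a
    1-d array is treated as a single chain (split into halves).  Values
    near 1 indicate the chains agree; constant draws give NaN.
    """
    draws = _split_chains(draws)
    if not _check(draws):
        warnings.warn("R-hat undefined: constant or too-short draws", stacklevel=2)
        return float("nan")
    z = _z_scale(draws)
    m, n = z.shape
    W = np.mean(np.var(z, axis=1, ddof=1))
    B = n * np.var(np.mean(z, axis=1), ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT."""
    n = x.shape[0]
    x = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real
    return acov / n


def _ess_core(chains: np.ndarray) -> float:
    """ESS of already split (and possibly rank-normalized) chains.

    Combines within- and between-chain variance, sums paired
    autocorrelations while the pair sums stay positive (Geyer initial
    positive sequence), then enforces monotone decay of the pair sums.
    """
    if not _check(chains):
        return float("nan")
    m, n = chains.shape
    acov = np.array([_autocov(c) for c in chains])
    chain_mean = chains.mean(axis=1)
    mean_var = np.mean(acov[:, 0]) * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += np.var(chain_mean, ddof=1)
    if var_plus == 0:
        return float("nan")
    rho = np.zeros(n)
    rho[0] = 1.0
    rho_even = 1.0
    rho_odd = 1.0 - (mean_var - np.mean(acov[:, 1])) / var_plus
    rho[1] = rho_odd
    t = 1
    while t < n - 3 and (rho_even + rho_odd) > 0:
        rho_even = 1.0 - (mean_var - np.mean(acov[:, t + 1])) / var_plus
        rho_odd = 1.0 - (mean_var - np.mean(acov[:, t + 2])) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho[max_t + 1] = rho_even
    # initial monotone condition on the pair sums
    t = 1
    while t <= max_t - 2:
        if rho[t + 1] + rho[t + 2] > rho[t - 1] + rho[t]:
            rho[t + 1] = (rho[t - 1] + rho[t]) / 2.0
            rho[t + 2] = rho[t + 1]
        t += 2
    S = m * n
    tau = -1.0 + 2.0 * np.sum(rho[: max_t + 1]) + rho[max_t + 1]
    tau = max(tau, 1.0 / np.log10(S))
    return float(S / tau)


def ess_bulk(draws) -> float:
    """Bulk effective sample size of rank-normalized split chains."""
    chains = _split_chains(draws)
    if not _check(chains):
        warnings.warn("ESS undefined: constant or too-short draws", stacklevel=2)
        return float("nan")
    return _ess_core(_z_scale(chains))


def _ess_quantile(draws: np.ndarray, prob: float) -> float:
    q = np.quantile(draws, prob)
    return _ess_core(_split_chains((draws <= q).astype(float)))


def ess_tail(draws) -> float:
    """Tail ESS: min of the 5%- and 95%-quantile indicator-sequence ESS."""
    chains = _split_chains(draws)
    if not _check(chains):
        warnings.warn("ESS undefined: constant or too-short draws", stacklevel=2)
        return float("nan")
    return float(min(_ess_quantile(chains, 0.05), _ess_quantile(chains, 0.95)))


def summarize(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: one row per parameter.

    Equal-tailed credible intervals at ``level`` (default 95%, i.e. the
    2.5% / 97.5% quantiles); diagnostics are NaN-flagged for degenerate
    (single-draw or constant) inputs.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, draws in fit.param_draws().items():
            flat = draws.reshape(-1)
            rows.append({
                "Parameter": name,
                "Estimate": float(np.mean(flat)),
                "Est_Error": float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
                "CI_Lower": float(np.quantile(flat, alpha)),
                "CI_Upper": float(np.quantile(flat, 1.0 - alpha)),
                "Rhat": split_rhat(draws),
                "Bulk_ESS": ess_bulk(draws),
                "Tail_ESS": ess_tail(draws),
            })
    return pd.DataFrame(rows).set_index("Parameter")
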