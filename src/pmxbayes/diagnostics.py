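"""Convergence diagnostics and posterior summaries.

R-hat and effective sample size follow the rank-normalized split
formulation: chains are split in half, draws are replaced by the normal
scores of their pooled fractional ranks, and the classic between/within
variance ratio

    R-hat = sqrt( (W (n-1)/n + B/n) / W )

is evaluated on the transformed draws; the reported R-hat is the larger of
the bulk value and the value on folded draws (|x - median|), which is
sensitive to scale mismatches.  Bulk ESS combines the per-chain
autocorrelation spectrum with Geyer's initial-monotone-sequence
truncation; tail ESS is the smaller ESS of the 5% and 95% quantile
exceedance indicators.  The Monte Carlo standard error of a posterior
mean is sd/sqrt(ESS_bulk), per the MCMC central limit theorem.

Summaries report mean, median, sd, mad (scaled by 1.4826 so it estimates
the sd of a normal), the 5th/95th quantiles (type-7 interpolation), R-hat
and bulk/tail ESS, with a warning whenever an ESS drops below 100 (the
point where sampling error stops being negligible next to posterior
spread).  ESS is reported uncapped: values above the draw count are
estimator noise on effectively independent chains and are noted, not
truncated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .hmc import ChainDraws

__all__ = [
    "split_chains",
    "rank_normalize",
    "split_rhat",
    "ess",
    "mcse_mean",
    "summarize",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "mean", "median", "sd", "mad", "q5", "q95", "rhat", "ess_bulk", "ess_tail",
]

_MAD_SCALE = 1.4826


def _as_array(draws, parameter=None) -> np.ndarray:
    if isinstance(draws, ChainDraws):
        if parameter is None:
            raise ValueError("a parameter name is required with ChainDraws input")
        return draws.param(parameter)
    a = np.asarray(draws, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("draws must be (n_chains, n_iter)")
    return a


def split_chains(x: np.ndarray) -> np.ndarray:
    """Halve each chain, doubling the chain count (drops an odd draw)."""
    m, n = x.shape
    half = n // 2
    return np.vstack([x[:, :half], x[:, n - half:]])


def rank_normalize(x: np.ndarray) -> np.ndarray:
    """Normal scores of pooled fractional ranks (Blom offsets 3/8, 1/4)."""
    shape = x.shape
    flat = x.reshape(-1)
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 1.0 / 4.0))
    return z.reshape(shape)


def _rhat_basic(z: np.ndarray) -> float:
    m, n = z.shape
    chain_means = z.mean(axis=1)
    chain_vars = z.var(axis=1, ddof=1)
    W = float(chain_vars.mean())
    B = n * chain_means.var(ddof=1)
    var_plus = W * (n - 1) / n + B / n
    return float(np.sqrt(var_plus / W))


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.all(x == x.reshape(-1)[0]))


def split_rhat(draws, parameter=None) -> float:
    """Rank-normalized split R-hat (max of bulk and folded variants).

    Requires at least 2 chains and 4 draws per chain; returns NaN (with a
    warning) for constant draws, where the statistic is undefined.
    """
    x = _as_array(draws, parameter)
    if x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("split R-hat needs >= 2 chains and >= 4 draws per chain")
    if _is_constant(x):
        warnings.warn("R-hat is undefined for constant draws", stacklevel=2)
        return float("nan")
    z = split_chains(x)
    bulk = _rhat_basic(rank_normalize(z))
    folded = _rhat_basic(rank_normalize(np.abs(z - np.median(z))))
    return max(bulk, folded)


def _autocov(z: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance (biased, /n) via FFT."""
    m, n = z.shape
    centered = z - z.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real
    return acov / n


def _ess_from_chains(z: np.ndarray) -> float:
    """Multi-chain ESS with Geyer initial-monotone truncation."""
    m, n = z.shape
    if _is_constant(z):
        return float("nan")
    acov = _autocov(z)
    chain_means = z.mean(axis=1)
    mean_var = float(acov[:, 0].mean()) * n / (n - 1)
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += float(chain_means.var(ddof=1))
    if var_plus == 0:
        return float("nan")

    mean_acov = acov.mean(axis=0)
    rho = np.zeros(n)
    rho_even = 1.0
    rho[0] = rho_even
    rho_odd = 1.0 - (mean_var - mean_acov[1]) / var_plus
    rho[1] = rho_odd
    # initial positive sequence: keep lag pairs while their sum is positive
    t = 1
    while t < n - 4 and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - mean_acov[t + 1]) / var_plus
        rho_odd = 1.0 - (mean_var - mean_acov[t + 2]) / var_plus
        if rho_even + rho_odd >= 0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:  # improve the estimate with the last admissible even lag
        rho[max_t + 1] = rho_even
    # Geyer initial monotone sequence: pair sums must be non-increasing
    for tt in range(1, max_t - 1, 2):
        if rho[tt + 1] + rho[tt + 2] > rho[tt - 1] + rho[tt]:
            rho[tt + 1] = (rho[tt - 1] + rho[tt]) / 2.0
            rho[tt + 2] = rho[tt + 1]
    total = m * n
    tau_hat = -1.0 + 2.0 * float(np.sum(rho[: max_t + 1])) + float(rho[max_t + 1])
    tau_hat = max(tau_hat, 1.0 / np.log10(total))  # antithetic-chain guard
    return float(total / tau_hat)


def ess(draws, parameter=None, kind: str = "bulk") -> float:
    """Effective sample size of split chains.

    ``kind="bulk"`` rank-normalizes the draws (central estimands);
    ``kind="tail"`` is the minimum ESS of the 5%/95% quantile exceedance
    indicators (tail estimands need many more draws for the same
    precision).
    """
    x = _as_array(draws, parameter)
    if x.shape[1] < 8:
        raise ValueError("too few draws to estimate ESS")
    if _is_constant(x):
        warnings.warn("ESS is undefined for constant draws", stacklevel=2)
        return float("nan")
    z = split_chains(x)
    if kind == "bulk":
        return _ess_from_chains(rank_normalize(z))
    if kind == "tail":
        out = []
        for q in (0.05, 0.95):
            cut = np.quantile(x, q)
            indicator = (z <= cut).astype(float)
            if _is_constant(indicator):
                out.append(float("nan"))
            else:
                out.append(_ess_from_chains(indicator))
        return float(np.nanmin(out))
    raise ValueError(f"kind must be 'bulk' or 'tail', got {kind!r}")


def mcse_mean(draws, parameter=None) -> float:
    """Monte Carlo standard error of the posterior mean: sd / sqrt(ESS)."""
    x = _as_array(draws, parameter)
    neff = ess(x, kind="bulk")
    return float(x.std(ddof=1) / np.sqrt(neff))


def summarize(draws: ChainDraws, parameters=None) -> pd.DataFrame:
    """Posterior summary table, one row per parameter.

    Columns: mean, median, sd, mad, q5, q95, rhat, ess_bulk, ess_tail.
    Warns when any ESS falls below 100.
    """
    if isinstance(draws, ChainDraws):
        names = parameters or draws.names
        arrays = {n: draws.param(n) for n in names}
    else:
        arrays = {k: _as_array(v) for k, v in dict(draws).items()}
        names = list(arrays)
    rows = []
    low_ess = []
    single_chain = next(iter(arrays.values())).shape[0] < 2
    for name in names:
        x = arrays[name]
        flat = x.reshape(-1)
        med = float(np.median(flat))
        can_diag = not single_chain and x.shape[1] >= 8 and not _is_constant(x)
        rhat = split_rhat(x) if can_diag else float("nan")
        eb = ess(x, kind="bulk") if can_diag else float("nan")
        et = ess(x, kind="tail") if can_diag else float("nan")
        rows.append(
            {
                "mean": float(flat.mean()),
                "median": med,
                "sd": float(flat.std(ddof=1)),
                "mad": _MAD_SCALE * float(np.median(np.abs(flat - med))),
                "q5": float(np.quantile(flat, 0.05)),
                "q95": float(np.quantile(flat, 0.95)),
                "rhat": rhat,
                "ess_bulk": eb,
                "ess_tail": et,
            }
        )
        if np.isfinite(eb) and eb < 100 or np.isfinite(et) and et < 100:
            low_ess.append(name)
    if low_ess:
        warnings.warn(
            f"effective sample size below 100 for {', '.join(low_ess)}; "
            "estimates for these quantities are imprecise - consider longer chains",
            stacklevel=2,
        )
    return pd.DataFrame(rows, index=pd.Index(names, name="parameter"), columns=SUMMARY_COLUMNS)
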