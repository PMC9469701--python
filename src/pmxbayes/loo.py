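"""Leave-one-out model comparison by Pareto-smoothed importance sampling.

The expected log pointwise predictive density under leave-one-out,

    elpd_loo = sum_i log p(y_i | y_-i),

would require n refits.  The PSIS estimator reweights the existing
posterior draws instead: for observation i the importance ratios are
r_s = 1 / p(y_i | theta_s); their largest 20% are fitted with a
generalized Pareto distribution, replaced by the fitted quantiles
(smoothing), truncated at the raw maximum, and used as weights w_s in

    elpd_i = log( sum_s w_s p(y_i | theta_s) / sum_s w_s ).

The fitted shape k-hat diagnoses reliability: k-hat > 0.7 means the
importance weights have too heavy a tail and the estimate for that
observation should not be trusted (a warning is emitted and the count is
reported).  The generalized Pareto fit uses the Zhang-Stephens
profile-posterior method with their small-sample shape regularization.

Model comparison sums pointwise elpd differences; its standard error is
sqrt(n * var(pointwise differences)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "LooResult",
    "gpd_fit",
    "psis_smooth",
    "pointwise_loglik",
    "psis_loo",
    "elpd_compare",
]

_TAIL_FRACTION = 0.2
_MIN_TAIL = 5
_KHAT_WARN = 0.7


@dataclass
class LooResult:
    """PSIS-LOO estimate with pointwise diagnostics.

    ``elpd_i`` and ``pareto_k`` have one entry per observation;
    ``elpd_loo = sum(elpd_i)`` and ``se = sqrt(n var(elpd_i))``.
    """

    elpd_loo: float
    se: float
    elpd_i: np.ndarray
    pareto_k: np.ndarray

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > _KHAT_WARN))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"elpd_i": self.elpd_i, "pareto_k": self.pareto_k},
            index=pd.RangeIndex(len(self.elpd_i), name="observation"),
        )


def gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto to exceedances ``x > 0``.

    Zhang & Stephens (2009) profile-posterior estimator: the shape k and
    scale sigma maximize a quadrature average over the profile likelihood
    of the reparameterized single parameter; the shape is then shrunk
    toward 0.5 with a weight of 10 pseudo-observations, which stabilizes
    small tails.  Returns (k, sigma).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < _MIN_TAIL:
        raise ValueError(f"need at least {_MIN_TAIL} tail samples, got {n}")
    xstar = x[int(n / 4 + 0.5) - 1]  # first-quartile order statistic
    if not (xstar > 0 and np.isfinite(x[-1])):
        raise ValueError("tail exceedances must be positive and finite")
    prior_bs, prior_k = 3.0, 10.0
    m_points = 30 + int(np.sqrt(n))
    jj = np.arange(1.0, m_points + 1.0)
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m_points / (jj - 0.5))) / (prior_bs * xstar)
    # profile log-likelihood of each candidate b (theta = -xi/sigma = -b)
    k_neg = np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)  # -k in ZS notation
    l_prof = n * (np.log(-b / k_neg) - k_neg - 1.0)
    w = np.exp(l_prof - l_prof.max())
    w /= w.sum()
    b_post = float(np.sum(b * w))
    xi = float(np.mean(np.log1p(-b_post * x)))  # tail index, >0 for heavy tails
    sigma = -xi / b_post
    xi = (n * xi + prior_k * 0.5) / (n + prior_k)  # shape shrinkage
    return xi, sigma


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_smooth(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one observation's log importance ratios.

    The largest 20% (at least 5) of the ratios are replaced by expected
    order statistics of the fitted generalized Pareto, truncated at the
    raw maximum.  Returns (smoothed log weights, k-hat).  When the tail is
    too short or has no spread the raw ratios are returned with k-hat 0.
    """
    lw = np.asarray(log_ratios, dtype=float).copy()
    s = lw.size
    n_tail = max(int(math.ceil(_TAIL_FRACTION * s)), _MIN_TAIL)
    if n_tail >= s:
        return lw, 0.0
    lw = lw - lw.max()  # stabilize; weights are invariant to a shift
    order = np.argsort(lw)
    tail_idx = order[-n_tail:]
    cutoff = lw[order[-n_tail - 1]]
    exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
    if np.ptp(exceed) <= 0:
        return lw, 0.0
    try:
        k, sigma = gpd_fit(exceed)
    except ValueError:
        # a tail too extreme to even fit: flag it, leave the ratios raw
        return lw, float("inf")
    if np.isfinite(k):
        p = (np.arange(1, n_tail + 1) - 0.5) / n_tail
        smoothed = np.log(_gpd_quantiles(p, k, sigma) + np.exp(cutoff))
        ranks = np.argsort(np.argsort(lw[tail_idx]))
        lw[tail_idx] = smoothed[ranks]
    lw = np.minimum(lw, 0.0)  # truncate at the raw maximum (which is 0 here)
    return lw, float(k)


def pointwise_loglik(draws, loglik_fn) -> np.ndarray:
    """Per-draw, per-observation log-likelihood matrix (S, n_obs).

    ``loglik_fn(values) -> vector over observations`` is evaluated at each
    posterior draw of a :class:`~pmxbayes.hmc.ChainDraws`; alternatively
    ``draws`` may already be an iterable of constrained value dicts.
    """
    from .hmc import ChainDraws

    if isinstance(draws, ChainDraws):
        flat = draws.draws.reshape(-1, draws.draws.shape[-1])
        dicts = ({n: row[j] for j, n in enumerate(draws.names)} for row in flat)
    else:
        dicts = iter(draws)
    rows = [np.asarray(loglik_fn(v), dtype=float) for v in dicts]
    return np.vstack(rows)


def psis_loo(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a (draws, observations) log-likelihood matrix."""
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("log-likelihood matrix must be (draws, observations)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite entries")
    S, n = ll.shape
    if S < 100:
        raise ValueError(f"PSIS-LOO needs at least 100 draws, got {S}")
    elpd_i = np.empty(n)
    khat = np.empty(n)
    for i in range(n):
        lw, k = psis_smooth(-ll[:, i])
        lw = lw - logsumexp(lw)
        elpd_i[i] = logsumexp(lw + ll[:, i])
        khat[i] = k
    n_bad = int(np.sum(khat > _KHAT_WARN))
    if n_bad:
        warnings.warn(
            f"{n_bad} of {n} observations have Pareto k-hat > {_KHAT_WARN}; "
            "their elpd contributions should not be trusted",
            stacklevel=2,
        )
    se = float(np.sqrt(n * np.var(elpd_i, ddof=1))) if n > 1 else 0.0
    return LooResult(float(np.sum(elpd_i)), se, elpd_i, khat)


def elpd_compare(a: LooResult, b: LooResult) -> tuple[float, float]:
    """Difference ``elpd_a - elpd_b`` and its standard error.

    Computed pointwise (the same observations must underlie both results),
    so shared sampling noise cancels: se = sqrt(n var(elpd_a_i - elpd_b_i)).
    """
    if len(a.elpd_i) != len(b.elpd_i):
        raise ValueError(
            f"model a has {len(a.elpd_i)} observations but model b has "
            f"{len(b.elpd_i)}; LOO comparison needs identical observations"
        )
    d = a.elpd_i - b.elpd_i
    n = d.size
    se = float(np.sqrt(n * np.var(d, ddof=1))) if n > 1 else 0.0
    return float(np.sum(d)), se
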