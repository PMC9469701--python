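"""Posterior predictive checks.

The check is the two-step simulation: draw parameters from their
posterior (here: reuse the MCMC draws), then draw replicate observations
from the likelihood conditional on each parameter draw.  Replicates pool
estimation uncertainty and measurement noise, so central credible bands
computed across replicates should cover the observed data at roughly
their nominal rate when the model is adequate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmc import ChainDraws
from .posterior import observed_rows, pk_concentrations_batch
from .simulate import rng_for

__all__ = ["posterior_predictive", "pk_posterior_predictive", "ppc_intervals"]


def posterior_predictive(draws: ChainDraws, simulate_obs, seed: int, thin: int = 1) -> np.ndarray:
    """Replicate matrix (draws, observations).

    ``simulate_obs(values, rng) -> vector`` draws one replicate dataset
    given one posterior draw's constrained values; the stream is seeded,
    so results are reproducible.
    """
    rng = rng_for(seed)
    flat = draws.draws.reshape(-1, draws.draws.shape[-1])[::thin]
    out = []
    for row in flat:
        values = {n: row[j] for j, n in enumerate(draws.names)}
        out.append(np.asarray(simulate_obs(values, rng), dtype=float))
    return np.vstack(out)


def pk_posterior_predictive(
    draws: ChainDraws,
    schedule,
    model: str = "twocpt",
    seed: int = 0,
    thin: int = 1,
) -> np.ndarray:
    """Replicates of the observed concentrations under the fitted PK model.

    Solves the schedule at each (thinned) posterior draw and applies the
    lognormal residual with that draw's sigma.  Vectorized over draws.
    """
    flat = draws.draws.reshape(-1, draws.draws.shape[-1])[::thin]
    values = {n: flat[:, j] for j, n in enumerate(draws.names)}
    conc = pk_concentrations_batch(schedule, values, model)
    sigma = np.atleast_1d(values["sigma"])[:, None]
    rng = rng_for(seed)
    if np.all(sigma == 0):
        return conc
    z = rng.standard_normal(conc.shape)
    return conc * np.exp(sigma * z)


def ppc_intervals(replicates: np.ndarray, probs=(0.5, 0.9), observed=None, times=None) -> pd.DataFrame:
    """Central credible bands per observation across replicates.

    Returns one row per observation with the replicate median and, for
    each probability p, ``lo{p}``/``hi{p}`` columns bounding the central
    p-interval.  Narrow bands are nested inside wide ones by
    construction.  Optional ``observed``/``times`` columns are attached
    for plotting or export.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2:
        raise ValueError("replicates must be (draws, observations)")
    if reps.shape[0] < 100:
        raise ValueError("need at least 100 replicates for stable intervals")
    data = {"median": np.median(reps, axis=0)}
    for p in sorted(probs):
        lo, hi = 0.5 - p / 2.0, 0.5 + p / 2.0
        tag = f"{int(round(100 * p))}"
        data[f"lo{tag}"] = np.quantile(reps, lo, axis=0)
        data[f"hi{tag}"] = np.quantile(reps, hi, axis=0)
    frame = pd.DataFrame(data)
    if times is not None:
        frame.insert(0, "time", np.asarray(times, dtype=float))
    if observed is not None:
        frame["observed"] = np.asarray(observed, dtype=float)
    return frame
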