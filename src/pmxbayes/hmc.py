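"""Adaptive Hamiltonian Monte Carlo with jittered path length.

The sampler runs leapfrog trajectories on the unconstrained space of a
:class:`~pmxbayes.posterior.Posterior`.  During warmup the step size is
tuned by Nesterov dual averaging toward a target acceptance statistic
(default 0.8) and a diagonal metric is estimated from draws in a windowed
schedule (short initial buffer, doubling estimation windows, terminal
step-size buffer), after which all tuning is frozen.  The number of
leapfrog steps per iteration is drawn so the total integration time
jitters uniformly around a configured path length, which avoids the
resonances of a fixed trajectory length without building trajectory
trees.  A transition is flagged divergent when the Hamiltonian
increases by more than a threshold (default 1000) or becomes non-finite
along the trajectory.

Everything is deterministic given the seed: per-chain generators are
spawned from a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .posterior import Posterior

__all__ = ["HmcSettings", "ChainDraws", "sample_hmc"]


@dataclass(frozen=True)
class HmcSettings:
    """Sampler tuning knobs.

    ``path_length`` is the nominal leapfrog integration time in
    unconstrained units; each iteration uses a trajectory length drawn
    uniformly in [0.5, 1.5] times this value.  ``divergence_threshold``
    is the Hamiltonian increase beyond which a transition is flagged
    divergent (an energy blow-up of the integrator).
    """

    target_accept: float = 0.8
    path_length: float = 1.2
    max_leapfrog: int = 64
    divergence_threshold: float = 1000.0
    init_buffer: float = 0.15
    term_buffer: float = 0.10


@dataclass
class ChainDraws:
    """Sampling-phase draws on the constrained scale.

    ``draws`` has shape (n_chains, n_iter, n_flat) with columns named by
    ``names``; ``unconstrained`` holds the matching sampler-space points,
    ``divergent``/``accept_stat`` the per-iteration divergence flag and
    acceptance statistic.  ``seed`` records the RNG seed for replay.
    """

    names: list[str]
    draws: np.ndarray
    unconstrained: np.ndarray
    divergent: np.ndarray
    accept_stat: np.ndarray
    seed: int
    n_warmup: int
    step_sizes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iter(self) -> int:
        return self.draws.shape[1]

    def param(self, name: str) -> np.ndarray:
        """Draws of one flattened parameter, shape (n_chains, n_iter)."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.draws[:, :, j]

    def pooled(self, name: str) -> np.ndarray:
        return self.param(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: chain, iteration, divergent flag, parameters."""
        c, n, _ = self.draws.shape
        frame = pd.DataFrame(self.draws.reshape(c * n, -1), columns=self.names)
        frame.insert(0, "chain", np.repeat(np.arange(c), n))
        frame.insert(1, "iteration", np.tile(np.arange(n), c))
        frame["divergent"] = self.divergent.reshape(-1).astype(int)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = 0, n_warmup: int = 0) -> "ChainDraws":
        chains = np.sort(frame["chain"].unique())
        names = [c for c in frame.columns if c not in ("chain", "iteration", "divergent")]
        draws = np.stack(
            [frame.loc[frame["chain"] == c, names].to_numpy(float) for c in chains]
        )
        div = (
            np.stack([frame.loc[frame["chain"] == c, "divergent"].to_numpy() for c in chains])
            if "divergent" in frame
            else np.zeros(draws.shape[:2], dtype=bool)
        )
        return cls(
            names=names,
            draws=draws,
            unconstrained=np.full_like(draws, np.nan),
            divergent=div.astype(bool),
            accept_stat=np.full(draws.shape[:2], np.nan),
            seed=seed,
            n_warmup=n_warmup,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChainDraws":
        return cls.from_frame(pd.read_csv(path))


def _leapfrog(grad, x, p, eps, n_steps, inv_metric):
    """Standard leapfrog; returns (x, p, ok) with ok False on a blow-up."""
    try:
        g = grad(x)
    except FloatingPointError:
        return x, p, False
    p = p + 0.5 * eps * g
    for step in range(n_steps):
        x = x + eps * inv_metric * p
        if not np.all(np.isfinite(x)):
            return x, p, False
        try:
            g = grad(x)
        except FloatingPointError:
            return x, p, False
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * g
    return x, p, True


def _find_reasonable_epsilon(logp, grad, x, inv_metric, rng):
    """Double/halve the step size until one leapfrog step crosses 50% accept."""
    eps = 1.0
    h0 = -logp(x)
    if not math.isfinite(h0):
        raise RuntimeError(
            "log density is not finite at the initial point; provide new inits"
        )
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_metric)
    h0 += 0.5 * float(np.sum(p0 * p0 * inv_metric))

    def dh(eps):
        x1, p1, ok = _leapfrog(grad, x.copy(), p0.copy(), eps, 1, inv_metric)
        if not ok:
            return -math.inf
        h1 = -logp(x1) + 0.5 * float(np.sum(p1 * p1 * inv_metric))
        return h0 - h1  # log acceptance ratio

    a = dh(eps)
    direction = 1 if a > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        a = dh(eps)
        if (direction == 1 and a <= math.log(0.5)) or (
            direction == -1 and a >= math.log(0.5)
        ):
            break
    return min(eps, 2.0)


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob):
        self.count += 1
        m = self.count
        frac = 1.0 / (m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return math.exp(self.log_eps)

    @property
    def eps_final(self):
        return math.exp(self.log_eps_bar)


def _metric_windows(n_warmup, init_frac, term_frac):
    """(start, end) spans of the metric estimation windows, Stan-style."""
    init = max(1, int(init_frac * n_warmup))
    term = max(1, int(term_frac * n_warmup))
    windows = []
    start = init
    size = 25
    while start + size < n_warmup - term:
        end = start + size
        if start + 3 * size >= n_warmup - term:  # absorb the remainder
            end = n_warmup - term
        windows.append((start, end))
        start = end
        size *= 2
    if not windows and n_warmup - term > init:
        windows.append((init, n_warmup - term))
    return windows


def sample_hmc(
    posterior: Posterior,
    n_chains: int = 4,
    inits=None,
    n_warmup: int = 1000,
    n_sampling: int = 1000,
    seed: int = 1,
    settings: HmcSettings = HmcSettings(),
) -> ChainDraws:
    """Run adaptive HMC and return sampling-phase draws.

    ``inits`` is a list of unconstrained start vectors, one per chain
    (see :func:`pmxbayes.paramspace.init_from_prior`).  Identical seeds
    yield bit-identical draws.
    """
    dim = posterior.dim
    if inits is None:
        from .paramspace import init_from_prior

        inits = init_from_prior(posterior.space, n_chains, seed)
    if len(inits) != n_chains:
        raise ValueError(f"need {n_chains} initial points, got {len(inits)}")

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_chains)]
    windows = _metric_windows(n_warmup, settings.init_buffer, settings.term_buffer)

    names = posterior.space.flat_names
    draws = np.empty((n_chains, n_sampling, dim))
    uncon = np.empty((n_chains, n_sampling, dim))
    divergent = np.zeros((n_chains, n_sampling), dtype=bool)
    accept_stat = np.empty((n_chains, n_sampling))
    step_sizes = np.empty(n_chains)

    logp = posterior.log_density
    grad = posterior.gradient

    for c in range(n_chains):
        rng = rngs[c]
        x = np.asarray(inits[c], dtype=float).copy()
        if x.shape != (dim,):
            raise ValueError(f"initial point {c} has wrong dimension")
        inv_metric = np.ones(dim)  # inverse metric = posterior variance estimate
        eps = _find_reasonable_epsilon(logp, grad, x, inv_metric, rng)
        da = _DualAveraging(eps, settings.target_accept)
        window_draws: list[np.ndarray] = []
        win_idx = 0
        n_accept_warmup = 0
        lp_x = logp(x)

        for it in range(n_warmup + n_sampling):
            warm = it < n_warmup
            eps_use = da.eps if warm else da.eps_final
            lam = settings.path_length * rng.uniform(0.5, 1.5)
            n_steps = int(np.clip(round(lam / eps_use), 1, settings.max_leapfrog))
            p0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
            h0 = -lp_x + 0.5 * float(np.sum(p0 * p0 * inv_metric))
            x1, p1, ok = _leapfrog(grad, x.copy(), p0.copy(), eps_use, n_steps, inv_metric)
            if ok:
                lp_x1 = logp(x1)
                h1 = -lp_x1 + 0.5 * float(np.sum(p1 * p1 * inv_metric))
                dh = h0 - h1
            else:
                dh = -math.inf
            # divergent = the integrator blew up: energy *increased* past the
            # threshold (or became non-finite); large energy drops are just
            # very good proposals and must remain acceptable
            div = (not math.isfinite(dh)) or -dh > settings.divergence_threshold
            a_prob = min(1.0, math.exp(min(dh, 0.0))) if math.isfinite(dh) else 0.0
            if (not div) and math.log(rng.uniform()) < dh:
                x, lp_x = x1, lp_x1
                if warm:
                    n_accept_warmup += 1
            if warm:
                da.update(a_prob)
                if win_idx < len(windows):
                    ws, we = windows[win_idx]
                    if ws <= it < we:
                        window_draws.append(x.copy())
                    if it == we - 1:
                        w = np.asarray(window_draws)
                        if w.shape[0] >= 5:
                            n = w.shape[0]
                            var = np.var(w, axis=0, ddof=1)
                            # regularize toward unit scale as Stan does
                            inv_metric = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                        window_draws = []
                        win_idx += 1
                        eps = _find_reasonable_epsilon(logp, grad, x, inv_metric, rng)
                        da = _DualAveraging(eps, settings.target_accept)
                if it == n_warmup - 1 and n_accept_warmup == 0:
                    raise RuntimeError(
                        "no proposal was accepted during warmup; the chain is stuck "
                        "at a pathological initial point - provide new inits"
                    )
            else:
                s = it - n_warmup
                values, _ = posterior.space.constrain(x)
                draws[c, s] = np.concatenate(
                    [np.atleast_1d(values[d.name]) for d in posterior.space.decls]
                )
                uncon[c, s] = x
                divergent[c, s] = div
                accept_stat[c, s] = a_prob
        step_sizes[c] = da.eps_final

    return ChainDraws(
        names=names,
        draws=draws,
        unconstrained=uncon,
        divergent=divergent,
        accept_stat=accept_stat,
        seed=seed,
        n_warmup=n_warmup,
        step_sizes=step_sizes,
    )
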