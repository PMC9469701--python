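"""Constrained parameter spaces with bound-respecting transforms.

Samplers work on an unconstrained vector; each declared parameter maps to
its constrained region through a bijection whose log-Jacobian is added to
the log joint density:

* lower bound L:   theta = L + exp(x),            log|J| = x
* upper bound U:   theta = U - exp(x),            log|J| = x
* both:            theta = L + (U-L) sigmoid(x),  log|J| = log(U-L) + log sig'(x)
* unbounded:       identity, log|J| = 0

Bounds may be expressions of previously declared parameters (evaluated
per draw), which is how the absorption rate can be kept above the slower
disposition rate to rule out flip-flop non-identifiability.  Priors are
declared per parameter (normal, truncated implicitly by the bounds, or
lognormal) and are proper, so chains can be initialized from prior draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NormalPrior",
    "LogNormalPrior",
    "ParamDecl",
    "ParameterSpace",
    "build_parameter_space",
    "init_from_prior",
    "slow_disposition_rate",
]

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


def slow_disposition_rate(CL, Q, Vcent, Vperi):
    """The slower hybrid rate lambda2 of the two-compartment disposition.

    Used as an expression lower bound on the population absorption rate:
    requiring ka > lambda2 pins absorption as the faster process and
    removes the flip-flop ambiguity.
    """
    k10 = CL / Vcent
    k12 = Q / Vcent
    k21 = Q / Vperi
    s = k10 + k12 + k21
    root = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + root)
    return np.where(lam1 > 0, k10 * k21 / np.where(lam1 > 0, lam1, 1.0), 0.0)


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior; implicitly truncated by the parameter's bounds."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("prior sigma must be > 0")

    def logpdf(self, x):
        with np.errstate(over="ignore"):
            z = (np.asarray(x, float) - self.mu) / self.sigma
            return -0.5 * z * z - math.log(self.sigma) - _HALF_LOG_2PI

    def sample(self, rng, size, lower=None, upper=None):
        a = -np.inf if lower is None else (lower - self.mu) / self.sigma
        b = np.inf if upper is None else (upper - self.mu) / self.sigma
        return stats.truncnorm.rvs(
            a, b, loc=self.mu, scale=self.sigma, size=size, random_state=rng
        )


@dataclass(frozen=True)
class LogNormalPrior:
    """LogNormal(mu, sigma) with mu on the log scale; mean exp(mu + sigma^2/2)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("prior sigma must be > 0")

    def logpdf(self, x):
        x = np.asarray(x, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.log(x)
            z = (lx - self.mu) / self.sigma
            out = -lx - 0.5 * z * z - math.log(self.sigma) - _HALF_LOG_2PI
        return np.where(x > 0, out, -np.inf)

    def sample(self, rng, size, lower=None, upper=None):
        # natural support already positive; respect tighter bounds by rejection
        draws = rng.lognormal(self.mu, self.sigma, size=size)
        lo = 0.0 if lower is None else lower
        hi = math.inf if upper is None else upper
        for _ in range(1000):
            bad = (draws <= lo) | (draws >= hi)
            if not np.any(bad):
                return draws
            draws = np.where(bad, rng.lognormal(self.mu, self.sigma, size=size), draws)
        raise RuntimeError("could not draw prior values inside the declared bounds")


Bound = float | str | Callable[[Mapping[str, np.ndarray]], float] | None


@dataclass(frozen=True)
class ParamDecl:
    """One parameter declaration: name, shape, bounds, prior.

    ``shape`` is () for a scalar or an int for a vector.  Bounds may be
    numbers or callables of the previously declared (constrained) values.
    ``prior=None`` declares an improper flat prior (allowed only when the
    model adds its own density term, e.g. per-subject parameters under a
    population prior).
    """

    name: str
    prior: NormalPrior | LogNormalPrior | None = None
    lower: Bound = None
    upper: Bound = None
    shape: int | tuple = ()

    @property
    def size(self) -> int:
        if self.shape == () or self.shape is None:
            return 1
        if isinstance(self.shape, int):
            return self.shape
        return int(np.prod(self.shape))


def _eval_bound(bound, values):
    if bound is None or isinstance(bound, (int, float)):
        return bound
    return bound(values)


class ParameterSpace:
    """Ordered parameter declarations with a bijective unconstraining map."""

    def __init__(self, decls: Sequence[ParamDecl]):
        names = [d.name for d in decls]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        compiled = []
        for i, d in enumerate(decls):  # expression bounds given as strings
            updates = {
                side: _compile_bound_expr(getattr(d, side), names[:i], d.name)
                for side in ("lower", "upper")
                if isinstance(getattr(d, side), str)
            }
            compiled.append(replace(d, **updates) if updates else d)
        self.decls = compiled
        self.names = names
        self.dim = sum(d.size for d in decls)
        self._offsets = np.cumsum([0] + [d.size for d in decls])

    @property
    def flat_names(self) -> list[str]:
        out = []
        for d in self.decls:
            if d.size == 1 and d.shape == ():
                out.append(d.name)
            else:
                out.extend(f"{d.name}[{i}]" for i in range(d.size))
        return out

    # -- transforms --------------------------------------------------------
    def constrain(self, x: np.ndarray) -> tuple[dict[str, np.ndarray], float]:
        """Map an unconstrained vector to constrained values + log-Jacobian."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(f"expected vector of length {self.dim}, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("unconstrained vector must be finite")
        values: dict[str, np.ndarray] = {}
        logj = 0.0
        err = np.seterr(over="ignore")
        for d, off in zip(self.decls, self._offsets):
            xi = x[off : off + d.size]
            lo = _eval_bound(d.lower, values)
            hi = _eval_bound(d.upper, values)
            if lo is not None and hi is not None:
                width = np.asarray(hi, float) - np.asarray(lo, float)
                sig = 1.0 / (1.0 + np.exp(-xi))
                theta = lo + width * sig
                logj += float(np.sum(np.log(width) + np.log(sig) + np.log1p(-sig)))
            elif lo is not None:
                theta = lo + np.exp(xi)
                logj += float(np.sum(xi))
            elif hi is not None:
                theta = hi - np.exp(xi)
                logj += float(np.sum(xi))
            else:
                theta = xi.copy()
            values[d.name] = theta[0] if d.shape == () else theta
        np.seterr(**err)
        return values, logj

    def unconstrain(self, values: Mapping[str, float | np.ndarray]) -> np.ndarray:
        """Inverse map; rejects values violating their declared bounds."""
        x = np.empty(self.dim)
        seen: dict[str, np.ndarray] = {}
        for d, off in zip(self.decls, self._offsets):
            theta = np.atleast_1d(np.asarray(values[d.name], dtype=float))
            if theta.size != d.size:
                raise ValueError(f"{d.name}: expected {d.size} values, got {theta.size}")
            lo = _eval_bound(d.lower, seen)
            hi = _eval_bound(d.upper, seen)
            if lo is not None and np.any(theta <= lo):
                raise ValueError(f"{d.name}={theta} violates lower bound {lo}")
            if hi is not None and np.any(theta >= hi):
                raise ValueError(f"{d.name}={theta} violates upper bound {hi}")
            if lo is not None and hi is not None:
                p = (theta - lo) / (np.asarray(hi, float) - np.asarray(lo, float))
                x[off : off + d.size] = np.log(p) - np.log1p(-p)
            elif lo is not None:
                x[off : off + d.size] = np.log(theta - lo)
            elif hi is not None:
                x[off : off + d.size] = np.log(hi - theta)
            else:
                x[off : off + d.size] = theta
            seen[d.name] = values[d.name]
        return x

    def constrain_batch(self, X: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Vectorized :meth:`constrain` over rows of ``X`` (B, dim)."""
        X = np.asarray(X, dtype=float)
        B = X.shape[0]

        def bc(bound):  # broadcast a scalar or per-row bound against (B, size)
            if bound is None:
                return None
            arr = np.asarray(bound, float)
            return arr[:, None] if arr.ndim == 1 else arr

        values: dict[str, np.ndarray] = {}
        logj = np.zeros(B)
        err = np.seterr(over="ignore")
        for d, off in zip(self.decls, self._offsets):
            xi = X[:, off : off + d.size]
            lo = bc(_eval_bound(d.lower, values))
            hi = bc(_eval_bound(d.upper, values))
            if lo is not None and hi is not None:
                width = hi - lo
                sig = 1.0 / (1.0 + np.exp(-xi))
                theta = lo + width * sig
                logj += np.sum(np.log(width) + np.log(sig) + np.log1p(-sig), axis=-1)
            elif lo is not None:
                theta = lo + np.exp(xi)
                logj += np.sum(xi, axis=-1)
            elif hi is not None:
                theta = hi - np.exp(xi)
                logj += np.sum(xi, axis=-1)
            else:
                theta = xi.copy()
            values[d.name] = theta[:, 0] if d.shape == () else theta
        np.seterr(**err)
        return values, logj

    # -- prior -------------------------------------------------------------
    def prior_logpdf(self, values: Mapping[str, np.ndarray]):
        """Sum of declared prior log-densities (flat priors contribute 0)."""
        total = 0.0
        for d in self.decls:
            if d.prior is not None:
                term = d.prior.logpdf(values[d.name])
                total = total + (np.sum(term, axis=-1) if d.size > 1 else term)
        return total

    def sample_prior(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """One joint draw from the declared priors, respecting bounds."""
        values: dict[str, np.ndarray] = {}
        for d in self.decls:
            if d.prior is None:
                raise ValueError(
                    f"parameter {d.name!r} has no proper prior; cannot draw initials"
                )
            lo = _eval_bound(d.lower, values)
            hi = _eval_bound(d.upper, values)
            draw = d.prior.sample(rng, d.size, lower=lo, upper=hi)
            values[d.name] = float(draw[0]) if d.shape == () else np.asarray(draw)
        return values


_PRIOR_FAMILIES = {"normal": NormalPrior, "lognormal": LogNormalPrior}
_EXPR_NAMESPACE = {
    "slow_disposition_rate": slow_disposition_rate,
    "log": np.log,
    "exp": np.exp,
    "sqrt": np.sqrt,
    "min": np.minimum,
    "max": np.maximum,
}


def _compile_bound_expr(expr: str, earlier: list[str], name: str):
    code = compile(expr, f"<bound of {name}>", "eval")
    for ref in code.co_names:
        if ref in (name,):
            raise ValueError(f"bound of {name!r} refers to itself (cyclic reference)")
        if ref not in earlier and ref not in _EXPR_NAMESPACE:
            raise ValueError(
                f"bound of {name!r} references {ref!r}, which is not declared earlier"
            )

    def bound(values):
        ns = dict(_EXPR_NAMESPACE)
        ns.update(values)
        return eval(code, {"__builtins__": {}}, ns)

    return bound


def build_parameter_space(config: Sequence[Mapping] | Mapping) -> ParameterSpace:
    """Build a :class:`ParameterSpace` from a configuration.

    ``config`` is a list of parameter entries (or a mapping with a
    ``parameters`` key), each with ``name`` and optional ``lower``/
    ``upper`` (number or expression string over earlier parameters),
    ``shape`` and ``prior: {family, mu, sigma}``.
    """
    if isinstance(config, Mapping):
        config = config["parameters"]
    decls: list[ParamDecl] = []
    earlier: list[str] = []
    for entry in config:
        name = entry["name"]
        prior = None
        if entry.get("prior") is not None:
            spec = dict(entry["prior"])
            family = spec.pop("family")
            if family not in _PRIOR_FAMILIES:
                raise ValueError(f"unknown prior family {family!r} for {name!r}")
            prior = _PRIOR_FAMILIES[family](**spec)
        bounds = {}
        for side in ("lower", "upper"):
            b = entry.get(side)
            if isinstance(b, str):
                b = _compile_bound_expr(b, earlier, name)
            bounds[side] = b
        shape = entry.get("shape", ())
        decls.append(ParamDecl(name=name, prior=prior, shape=shape, **bounds))
        earlier.append(name)
    return ParameterSpace(decls)


def init_from_prior(space: ParameterSpace, n_chains: int, seed: int) -> list[np.ndarray]:
    """Independent prior draws per chain, mapped to unconstrained space."""
    rng = np.random.default_rng(seed)
    return [space.unconstrain(space.sample_prior(rng)) for _ in range(n_chains)]
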