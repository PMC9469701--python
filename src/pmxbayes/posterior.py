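"""Unnormalized log joint density assembly and gradients.

A :class:`Posterior` bundles a :class:`~pmxbayes.paramspace.ParameterSpace`
with a log-likelihood callable: evaluating at an unconstrained vector x
yields

    log p(D, theta(x)) + log|J(x)|
      = sum(prior log-densities) + log-likelihood + log-Jacobian.

A solver failure at a proposed parameter value maps to ``-inf`` (the
sampler simply rejects) rather than an exception, which keeps early-phase
MCMC exploration robust.  Gradients default to central finite differences
with per-coordinate step ``cbrt(eps) * max(1, |x_i|)``, evaluated through
the batched density so one gradient costs a single vectorized sweep; an
exact-gradient provider can be plugged in via ``gradient_fn``.

Builders are provided for the single-subject one/two-compartment
concentration model and for the allometrically scaled population model.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping

import numpy as np

from . import fastpath
from .events import EventSchedule, observation_view
from .models import allometric_params, lognormal_loglik, population_logprior
from .odes import OdeError
from .paramspace import LogNormalPrior, NormalPrior, ParamDecl, ParameterSpace
from .solvers import OneCptParams, SolverError, TwoCptParams, solve_schedule_analytic

__all__ = [
    "Posterior",
    "log_joint",
    "grad_log_joint",
    "build_pk_posterior",
    "build_population_posterior",
    "default_twocpt_space",
    "default_onecpt_space",
]

_FD_STEP = float(np.cbrt(np.finfo(float).eps))


class Posterior:
    """Log joint density of data and parameters, on unconstrained space."""

    def __init__(
        self,
        space: ParameterSpace,
        loglik: Callable[[Mapping], float],
        loglik_batch: Callable[[Mapping], np.ndarray] | None = None,
        gradient_fn: Callable[[np.ndarray], np.ndarray] | None = None,
        data=None,
    ):
        self.space = space
        self._loglik = loglik
        self._loglik_batch = loglik_batch
        self._gradient_fn = gradient_fn
        self.data = data

    @property
    def dim(self) -> int:
        return self.space.dim

    # -- density -----------------------------------------------------------
    def prior_part(self, x: np.ndarray) -> float:
        values, logj = self.space.constrain(x)
        return float(self.space.prior_logpdf(values)) + logj

    def likelihood_part(self, x: np.ndarray) -> float:
        values, _ = self.space.constrain(x)
        try:
            return float(self._loglik(values))
        except (SolverError, OdeError, ValueError, FloatingPointError, OverflowError):
            return -math.inf

    def log_density(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("unconstrained vector must be finite")
        values, logj = self.space.constrain(x)
        prior = float(self.space.prior_logpdf(values))
        if not math.isfinite(prior):
            return -math.inf
        try:
            lik = float(self._loglik(values))
        except (SolverError, OdeError, ValueError, FloatingPointError, OverflowError):
            # a solver failure at a proposed theta is a rejection, not a crash
            return -math.inf
        if not math.isfinite(lik):
            return -math.inf
        return prior + lik + logj

    def log_density_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._loglik_batch is None:
            return np.array([self.log_density(x) for x in X])
        values, logj = self.space.constrain_batch(X)
        prior = np.asarray(self.space.prior_logpdf(values), dtype=float)
        with np.errstate(all="ignore"):
            lik = np.asarray(self._loglik_batch(values), dtype=float)
        out = prior + lik + logj
        return np.where(np.isfinite(out), out, -np.inf)

    # -- gradient ----------------------------------------------------------
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """d/dx log_density; central differences unless a provider is set."""
        if self._gradient_fn is not None:
            return np.asarray(self._gradient_fn(x), dtype=float)
        x = np.asarray(x, dtype=float)
        h = _FD_STEP * np.maximum(1.0, np.abs(x))
        stencil = np.repeat(x[None, :], 2 * x.size, axis=0)
        idx = np.arange(x.size)
        stencil[2 * idx, idx] += h
        stencil[2 * idx + 1, idx] -= h
        vals = self.log_density_batch(stencil)
        if not np.all(np.isfinite(vals)):
            bad = int(np.where(~np.isfinite(vals))[0][0] // 2)
            raise FloatingPointError(
                f"log joint density is not finite within the finite-difference "
                f"stencil of coordinate {bad} ({self.space.flat_names[bad]})"
            )
        return (vals[2 * idx] - vals[2 * idx + 1]) / (2.0 * h)


def log_joint(posterior: Posterior, x: np.ndarray) -> float:
    """Module-level alias for :meth:`Posterior.log_density`."""
    return posterior.log_density(x)


def grad_log_joint(posterior: Posterior, x: np.ndarray) -> np.ndarray:
    return posterior.gradient(x)


# ---------------------------------------------------------------------------
# single-subject concentration model
# ---------------------------------------------------------------------------

_TWOCPT_NAMES = ("CL", "Q", "Vcent", "Vperi", "ka")
_ONECPT_NAMES = ("CL", "Vcent", "ka")


def default_twocpt_space() -> ParameterSpace:
    """Weakly informative priors for the two-compartment concentration model.

    Centered on typical adult values (CL 10 L/h, Q 15 L/h, Vcent 35 L,
    Vperi 105 L, ka 2 /h) with generous lognormal spread; sigma has a
    half-normal prior.
    """
    return ParameterSpace(
        [
            ParamDecl("CL", LogNormalPrior(math.log(10.0), 0.25), lower=0.0),
            ParamDecl("Q", LogNormalPrior(math.log(15.0), 0.5), lower=0.0),
            ParamDecl("Vcent", LogNormalPrior(math.log(35.0), 0.25), lower=0.0),
            ParamDecl("Vperi", LogNormalPrior(math.log(105.0), 0.5), lower=0.0),
            ParamDecl("ka", LogNormalPrior(math.log(2.0), 1.0), lower=0.0),
            ParamDecl("sigma", NormalPrior(0.0, 0.5), lower=0.0),
        ]
    )


def default_onecpt_space() -> ParameterSpace:
    return ParameterSpace(
        [
            ParamDecl("CL", LogNormalPrior(math.log(10.0), 0.25), lower=0.0),
            ParamDecl("Vcent", LogNormalPrior(math.log(35.0), 0.5), lower=0.0),
            ParamDecl("ka", LogNormalPrior(math.log(2.0), 1.0), lower=0.0),
            ParamDecl("sigma", NormalPrior(0.0, 0.5), lower=0.0),
        ]
    )


def observed_rows(schedule: EventSchedule) -> tuple[np.ndarray, np.ndarray]:
    """(indices, dv) of measurement rows that carry a recorded value."""
    view = observation_view(schedule)
    idx = [
        i
        for sid in schedule.subjects
        for i in view[sid]
        if schedule.records[i].dv is not None
    ]
    idx = np.asarray(idx, dtype=int)
    dv = np.array([schedule.records[i].dv for i in idx], dtype=float)
    return idx, dv


def _params_from_values(values, model: str):
    cls = TwoCptParams if model == "twocpt" else OneCptParams
    names = _TWOCPT_NAMES if model == "twocpt" else _ONECPT_NAMES
    return cls(**{n: float(values[n]) for n in names})


def pk_concentrations(schedule, values, model: str) -> np.ndarray:
    """Model concentration at the observed rows for one parameter set."""
    idx, _ = observed_rows(schedule)
    p = _params_from_values(values, model)
    sol = solve_schedule_analytic(schedule, p, model=model)
    return sol.amounts[p.central_index, idx] / p.Vcent


def pk_concentrations_batch(schedule, values, model: str) -> np.ndarray:
    """Batched concentrations (B, n_obs); falls back per row when needed."""
    idx, _ = observed_rows(schedule)
    if fastpath.is_superposable(schedule):
        dose_t, dose_amt, _, _ = fastpath.dose_and_obs_times(schedule)
        obs_t = np.array([schedule.records[i].time for i in idx])
        kwargs = dict(CL=values["CL"], Vcent=values["Vcent"], ka=values["ka"])
        if model == "twocpt":
            kwargs.update(Q=values["Q"], Vperi=values["Vperi"])
        u, ok = fastpath.central_amounts_batch(model, dose_t, dose_amt, obs_t, **kwargs)
        conc = u / np.atleast_1d(np.asarray(values["Vcent"], float))[:, None]
        if not np.all(ok):
            for b in np.where(~ok)[0]:
                one = {k: np.atleast_1d(v)[b] for k, v in values.items()}
                try:
                    conc[b] = pk_concentrations(schedule, one, model)
                except (ValueError, SolverError):  # invalid proposal -> reject
                    conc[b] = np.nan
        return conc
    B = np.atleast_1d(np.asarray(values["CL"], float)).shape[0]
    return np.stack(
        [
            pk_concentrations(schedule, {k: np.atleast_1d(v)[b] for k, v in values.items()}, model)
            for b in range(B)
        ]
    )


def build_pk_posterior(
    schedule: EventSchedule,
    space: ParameterSpace | None = None,
    model: str = "twocpt",
) -> Posterior:
    """Posterior for a single-subject concentration dataset.

    The likelihood maps the named PK parameters through the analytic
    schedule solver to central concentrations at the observed rows and
    scores the recorded dv values with a lognormal residual of scale
    ``sigma``.
    """
    if space is None:
        space = default_twocpt_space() if model == "twocpt" else default_onecpt_space()
    idx, dv = observed_rows(schedule)
    if idx.size == 0:
        raise ValueError("schedule carries no recorded observations (dv)")
    log_dv = np.log(dv)
    const = float(np.sum(-log_dv)) - dv.size * 0.5 * math.log(2.0 * math.pi)

    def loglik(values) -> float:
        conc = pk_concentrations(schedule, values, model)
        if np.any(conc <= 0):
            return -math.inf
        sigma = float(values["sigma"])
        return lognormal_loglik(dv, conc, sigma)

    def loglik_batch(values) -> np.ndarray:
        conc = pk_concentrations_batch(schedule, values, model)
        sigma = np.atleast_1d(np.asarray(values["sigma"], float))[:, None]
        with np.errstate(all="ignore"):
            z = log_dv[None, :] - np.log(conc)
            terms = -np.log(sigma) - z * z / (2.0 * sigma**2)
            out = const + np.sum(terms, axis=1)
        return np.where(np.all(conc > 0, axis=1), out, -np.inf)

    return Posterior(space, loglik, loglik_batch, data=schedule)


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------


def default_population_space(n_subjects: int) -> ParameterSpace:
    """Population-level priors plus flat-prior subject parameter vectors.

    Subject parameters get their density from the lognormal population
    term inside the likelihood, not from a declared prior.
    """
    decls = [
        ParamDecl("CL_pop", LogNormalPrior(math.log(10.0), 0.25), lower=0.0),
        ParamDecl("Q_pop", LogNormalPrior(math.log(15.0), 0.5), lower=0.0),
        ParamDecl("Vcent_pop", LogNormalPrior(math.log(35.0), 0.25), lower=0.0),
        ParamDecl("Vperi_pop", LogNormalPrior(math.log(105.0), 0.5), lower=0.0),
        ParamDecl("ka_pop", LogNormalPrior(math.log(2.0), 1.0),
                  lower="slow_disposition_rate(CL_pop, Q_pop, Vcent_pop, Vperi_pop)"),
        ParamDecl("omega", NormalPrior(0.0, 0.5), lower=0.0, shape=5),
        ParamDecl("sigma", NormalPrior(0.0, 0.5), lower=0.0),
        ParamDecl("theta", None, lower=0.0, shape=5 * n_subjects),
    ]
    return ParameterSpace(decls)


def build_population_posterior(
    schedule: EventSchedule,
    space: ParameterSpace | None = None,
    weight_covariate: str = "wt",
    ref_weight: float = 70.0,
    exp_clearance: float = 0.75,
    exp_volume: float = 1.0,
) -> Posterior:
    """Posterior for a multi-subject two-compartment dataset.

    Subject parameters ``theta`` (flattened J x 5, ordered CL, Q, Vcent,
    Vperi, ka per subject) follow a diagonal lognormal population prior
    around the ``*_pop`` typical values; clearances and volumes are
    allometrically scaled by each subject's body weight covariate before
    solving.
    """
    subjects = schedule.subjects
    J = len(subjects)
    if space is None:
        space = default_population_space(J)
    weights = []
    for sid in subjects:
        recs = schedule.subject_records(sid)
        w = next((r.covariates[weight_covariate] for r in recs if weight_covariate in r.covariates), None)
        weights.append(ref_weight if w is None else float(w))
    sub_obs = []
    for sid in subjects:
        sl = schedule.subject_slice(sid)
        sub_sched = EventSchedule(schedule.records[sl], F=schedule.F, tlag=schedule.tlag)
        idx, dv = observed_rows(sub_sched)
        sub_obs.append((sub_sched, idx, dv))

    def loglik(values) -> float:
        theta = np.asarray(values["theta"], float).reshape(J, 5)
        theta_pop = np.array(
            [values["CL_pop"], values["Q_pop"], values["Vcent_pop"],
             values["Vperi_pop"], values["ka_pop"]], dtype=float
        )
        omega = np.asarray(values["omega"], float)
        total = population_logprior(theta, theta_pop, omega)
        sigma = float(values["sigma"])
        for j, (sub_sched, idx, dv) in enumerate(sub_obs):
            norm = TwoCptParams(*theta[j])
            p = allometric_params(norm, weights[j], exp_clearance, exp_volume, ref_weight)
            sol = solve_schedule_analytic(sub_sched, p)
            conc = sol.amounts[p.central_index, idx] / p.Vcent
            if np.any(conc <= 0):
                return -math.inf
            total += lognormal_loglik(dv, conc, sigma)
        return total

    return Posterior(space, loglik, data=schedule)
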