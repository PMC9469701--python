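"""Concrete model components: myelosuppression dynamics and statistical terms.

The Friberg-Karlsson semimechanistic neutropenia model links drug exposure
to circulating absolute neutrophil count (ANC).  A proliferating pool
feeds three transit compartments and finally the circulating pool; a
feedback term ``(Circ0 / Circ)^gamma`` restores the baseline, and the drug
reduces proliferation through a linear effect ``Edrug = min(alpha * c, 1)``
on the proliferation rate, where ``c`` is the central drug concentration.
The mean maturation time through the chain is ``MTT = (n+1)/ktr`` with
``n = 3`` transit compartments, and the baseline is an equilibrium because
``kprol = ktr``.

The PD states are kept as differences from baseline (initial condition
exactly zero); inside the dynamics the actual counts are floored at
machine epsilon so that the right-hand side stays finite for any state an
adaptive integrator or an early-phase MCMC iteration may propose.

Measurement models are lognormal for both the concentration and ANC
streams, each with its own residual scale.  The population layer places
independent lognormal priors on each subject's parameters around the
population-typical value (diagonal covariance) and applies conventional
allometric body-weight scaling to clearances and volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .solvers import OneCptParams, SolutionMatrix, TwoCptParams

__all__ = [
    "FKParams",
    "N_TRANSIT",
    "EPS",
    "mtt_to_ktr",
    "ktr_to_mtt",
    "fk_rhs",
    "predicted_concentration",
    "lognormal_loglik",
    "allometric_params",
    "population_logprior",
]

#: number of transit compartments in the maturation chain
N_TRANSIT = 3
#: positivity floor used inside the PD dynamics (double machine epsilon)
EPS = float(np.finfo(float).eps)
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


def mtt_to_ktr(mtt: float, n_transit: int = N_TRANSIT) -> float:
    """Transit rate constant (1/h) from the mean transit time (h): (n+1)/MTT."""
    if not mtt > 0:
        raise ValueError(f"MTT must be > 0, got {mtt}")
    return (n_transit + 1) / mtt


def ktr_to_mtt(ktr: float, n_transit: int = N_TRANSIT) -> float:
    if not ktr > 0:
        raise ValueError(f"ktr must be > 0, got {ktr}")
    return (n_transit + 1) / ktr


@dataclass(frozen=True)
class FKParams:
    """Friberg-Karlsson parameters.

    mtt: mean transit time (h); circ0: baseline circulating neutrophil
    count (ANC units); alpha: linear drug-effect slope (per mg/L);
    gamma: feedback exponent (dimensionless).
    """

    mtt: float
    circ0: float
    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.mtt > 0:
            raise ValueError(f"mtt must be > 0, got {self.mtt}")
        if not self.circ0 > 0:
            raise ValueError(f"circ0 must be > 0, got {self.circ0}")
        if not self.alpha >= 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @property
    def ktr(self) -> float:
        return mtt_to_ktr(self.mtt)

    @property
    def kprol(self) -> float:
        # equal to ktr so that the drug-free baseline is an equilibrium
        return self.ktr

    n_states: int = 5  # prol, transit1..3, circ


def fk_rhs(t, y_pd, y_pk, p: FKParams, vcent: float) -> np.ndarray:
    """Baseline-shifted Friberg-Karlsson derivatives.

    ``y_pd`` holds (prol, transit1, transit2, transit3, circ) as
    differences from ``circ0``; ``y_pk`` is the PK state whose central
    amount (index 1) divided by ``vcent`` gives the concentration driving
    ``Edrug``.  Actual counts are floored at machine epsilon and the
    concentration at zero, so the derivative is finite for implausible
    proposals; the cap ``Edrug <= 1`` keeps the feedback loop from
    flipping sign at extreme exposure.
    """
    a = np.maximum(np.asarray(y_pd, dtype=float) + p.circ0, EPS)
    chat = max(float(y_pk[1]) / vcent, 0.0)
    edrug = min(p.alpha * chat, 1.0)
    ktr = p.ktr
    dy = np.empty(5)
    dy[0] = p.kprol * a[0] * (1.0 - edrug) * (p.circ0 / a[4]) ** p.gamma - ktr * a[0]
    dy[1] = ktr * (a[0] - a[1])
    dy[2] = ktr * (a[1] - a[2])
    dy[3] = ktr * (a[2] - a[3])
    dy[4] = ktr * (a[3] - a[4])
    return dy


def predicted_concentration(
    sol: SolutionMatrix | np.ndarray,
    vcent: float,
    obs: np.ndarray,
    central_index: int = 1,
) -> np.ndarray:
    """Central-compartment concentration (mg/L) at the given event indices."""
    if not vcent > 0:
        raise ValueError(f"Vcent must be > 0, got {vcent}")
    amounts = sol.amounts if isinstance(sol, SolutionMatrix) else np.asarray(sol)
    obs = np.asarray(obs, dtype=int)
    if obs.size == 0:
        return np.empty(0)
    return amounts[central_index, obs] / vcent


def lognormal_loglik(y, yhat, sigma) -> float:
    """Lognormal measurement log-density, summed over observations.

    ``log y ~ Normal(log yhat, sigma)``; each term is
    ``-log y - log sigma - log(2 pi)/2 - (log y - log yhat)^2 / (2 sigma^2)``.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    yhat = np.atleast_1d(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError(f"y {y.shape} and yhat {yhat.shape} differ in shape")
    if np.any(y <= 0):
        raise ValueError("observations must be strictly positive for a lognormal model")
    if np.any(yhat <= 0):
        raise ValueError("predictions must be strictly positive for a lognormal model")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    z = np.log(y) - np.log(yhat)
    return float(
        np.sum(-np.log(y) - math.log(sigma) - _HALF_LOG_2PI - z * z / (2.0 * sigma**2))
    )


def allometric_params(
    theta_norm: TwoCptParams | OneCptParams,
    weight: float,
    exp_clearance: float = 0.75,
    exp_volume: float = 1.0,
    ref_weight: float = 70.0,
) -> TwoCptParams | OneCptParams:
    """Body-weight scaling of a normalized parameter set.

    Clearances scale as ``(weight/ref)^0.75`` and volumes as
    ``(weight/ref)^1`` by default; the absorption rate ka is not scaled.
    At ``weight == ref_weight`` this is the identity.
    """
    if not weight > 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    w = weight / ref_weight
    fc = w**exp_clearance
    fv = w**exp_volume
    if isinstance(theta_norm, TwoCptParams):
        return _dc_replace(
            theta_norm,
            CL=theta_norm.CL * fc,
            Q=theta_norm.Q * fc,
            Vcent=theta_norm.Vcent * fv,
            Vperi=theta_norm.Vperi * fv,
        )
    if isinstance(theta_norm, OneCptParams):
        return _dc_replace(
            theta_norm, CL=theta_norm.CL * fc, Vcent=theta_norm.Vcent * fv
        )
    raise TypeError(f"unsupported parameter type {type(theta_norm).__name__}")


def population_logprior(theta, theta_pop, omega) -> float:
    """Log-density of per-subject parameters under the population model.

    ``theta`` is (n_subjects, n_dims) of positive subject parameters,
    ``theta_pop`` the population-typical values and ``omega`` the log-scale
    standard deviations (diagonal covariance):
    ``theta[j, d] ~ LogNormal(log theta_pop[d], omega[d])`` independently.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    theta_pop = np.asarray(theta_pop, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if theta.shape[1] != theta_pop.shape[0] or theta_pop.shape != omega.shape:
        raise ValueError(
            f"dimension mismatch: theta {theta.shape}, theta_pop {theta_pop.shape}, "
            f"omega {omega.shape}"
        )
    if np.any(theta <= 0) or np.any(theta_pop <= 0):
        raise ValueError("population parameters must be strictly positive")
    if np.any(omega <= 0):
        raise ValueError("omega entries must be strictly positive")
    z = np.log(theta) - np.log(theta_pop)
    terms = -np.log(theta) - np.log(omega) - _HALF_LOG_2PI - z * z / (2.0 * omega**2)
    return float(np.sum(terms))
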