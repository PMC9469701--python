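"""Closed-form propagation of linear compartment models over event schedules.

The one- and two-compartment models with first-order absorption admit
exact solutions: the disposition system has hybrid rate constants
(eigen-rates) ``lambda1 >= lambda2 > 0`` solving

    lambda^2 - (k10 + k12 + k21) lambda + k10 k21 = 0,

with micro-constants ``k10 = CL/Vcent``, ``k12 = Q/Vcent``,
``k21 = Q/Vperi``.  Interval propagation diagonalizes the rate matrix in
closed form; near-degenerate spectra (absorption rate colliding with a
hybrid rate, or ``Q ~ 0``) fall back to a matrix-exponential propagator so
that a single code path handles repeated eigenvalues.  Constant zero-order
inputs (infusions) are handled exactly in both paths, without requiring an
invertible rate matrix.

``solve_schedule_analytic`` walks the solve plan produced by
:func:`pmxbayes.events.event_grid`, yielding a :class:`SolutionMatrix` of
drug amounts per compartment at every event time.  Dose rows report the
post-dose state; steady-state rows (ss=1) re-initialize the subject from
the periodic steady state of their dosing regimen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .events import EventSchedule, EventValidationError, event_grid, to_frame

__all__ = [
    "TwoCptParams",
    "OneCptParams",
    "SolutionMatrix",
    "SolverError",
    "hybrid_constants",
    "advance_interval_analytic",
    "matrix_exponential_advance",
    "steady_state_state",
    "solve_schedule_analytic",
    "execute_plan",
]

_DEGENERACY_RTOL = 1e-8  # relative eigenvalue separation below which we use expm


class SolverError(RuntimeError):
    """Raised when a schedule cannot be solved (e.g. no steady state)."""


@dataclass(frozen=True)
class TwoCptParams:
    """Two-compartment model with first-order absorption.

    CL: elimination clearance (L/h); Q: intercompartmental clearance (L/h);
    Vcent/Vperi: central/peripheral volumes (L); ka: absorption rate (1/h).
    State order is (gut, central, peripheral).  CL and Q may be zero
    (degenerate but well-defined dynamics); volumes and ka must be positive.
    """

    CL: float
    Q: float
    Vcent: float
    Vperi: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("Vcent", "Vperi", "ka"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("CL", "Q"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("CL", "Q", "Vcent", "Vperi", "ka"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    n_cmt: int = 3
    central_index: int = 1

    def micro_constants(self) -> tuple[float, float, float]:
        return self.CL / self.Vcent, self.Q / self.Vcent, self.Q / self.Vperi

    def rate_matrix(self) -> np.ndarray:
        k10, k12, k21 = self.micro_constants()
        ka = self.ka
        return np.array(
            [
                [-ka, 0.0, 0.0],
                [ka, -(k10 + k12), k21],
                [0.0, k12, -k21],
            ]
        )


@dataclass(frozen=True)
class OneCptParams:
    """One-compartment model with first-order absorption; states (gut, central)."""

    CL: float
    Vcent: float
    ka: float

    def __post_init__(self) -> None:
        if not self.Vcent > 0:
            raise ValueError(f"Vcent must be > 0, got {self.Vcent}")
        if not self.ka > 0:
            raise ValueError(f"ka must be > 0, got {self.ka}")
        if not self.CL >= 0:
            raise ValueError(f"CL must be >= 0, got {self.CL}")

    n_cmt: int = 2
    central_index: int = 1

    def rate_matrix(self) -> np.ndarray:
        k10 = self.CL / self.Vcent
        return np.array([[-self.ka, 0.0], [self.ka, -k10]])


def hybrid_constants(p: TwoCptParams) -> tuple[float, float, float, float, float]:
    """Micro and hybrid rate constants ``(k10, k12, k21, lambda1, lambda2)``.

    The hybrid rates are the roots of
    ``lambda^2 - (k10+k12+k21) lambda + k10 k21``, returned with
    ``lambda1 >= lambda2``; they satisfy the Vieta identities
    ``lambda1 * lambda2 = k10 * k21`` and
    ``lambda1 + lambda2 = k10 + k12 + k21``.
    """
    k10, k12, k21 = p.micro_constants()
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = s * s - 4.0 * prod
    if disc < 0:  # numerically impossible for non-negative rates; guard anyway
        disc = 0.0
    root = math.sqrt(disc)
    lam1 = 0.5 * (s + root)
    # computing lambda2 via the product avoids cancellation when lam1 >> lam2
    lam2 = prod / lam1 if lam1 > 0 else 0.0
    return k10, k12, k21, lam1, lam2


def _phi(rates: np.ndarray, dt: float) -> np.ndarray:
    """(1 - exp(-r dt))/r with the r -> 0 limit dt, elementwise."""
    out = np.empty_like(rates)
    small = np.abs(rates) * dt < 1e-12
    nz = ~small
    out[nz] = -np.expm1(-rates[nz] * dt) / rates[nz]
    out[small] = dt * (1.0 - 0.5 * rates[small] * dt)
    return out


class _EigenPropagator:
    """Exact interval propagation via a closed-form eigendecomposition."""

    def __init__(self, rates: np.ndarray, V: np.ndarray, Vinv: np.ndarray):
        self.rates = rates  # positive decay rates (eigenvalues of -A)
        self.V = V
        self.Vinv = Vinv

    def advance(self, u: np.ndarray, dt: float, infusion: np.ndarray | None = None) -> np.ndarray:
        if dt == 0:
            return np.array(u, dtype=float)
        w = self.Vinv @ u
        decay = np.exp(-self.rates * dt)
        w = w * decay
        if infusion is not None and np.any(infusion):
            beta = self.Vinv @ infusion
            w = w + beta * _phi(self.rates, dt)
        return self.V @ w


class _MatexpPropagator:
    """Fallback propagator for (near-)degenerate spectra; exact via expm."""

    def __init__(self, A: np.ndarray):
        self.A = np.asarray(A, dtype=float)

    def advance(self, u: np.ndarray, dt: float, infusion: np.ndarray | None = None) -> np.ndarray:
        if dt == 0:
            return np.array(u, dtype=float)
        return matrix_exponential_advance(self.A, u, dt, infusion)


def _build_propagator(p: TwoCptParams | OneCptParams):
    if isinstance(p, OneCptParams):
        ka, k10 = p.ka, p.CL / p.Vcent
        scale = ka + k10
        if abs(ka - k10) <= _DEGENERACY_RTOL * scale:
            return _MatexpPropagator(p.rate_matrix())
        V = np.array([[1.0, 0.0], [ka / (k10 - ka), 1.0]])
        Vinv = np.array([[1.0, 0.0], [-ka / (k10 - ka), 1.0]])
        return _EigenPropagator(np.array([ka, k10]), V, Vinv)

    k10, k12, k21, lam1, lam2 = hybrid_constants(p)
    ka = p.ka
    scale = ka + lam1 + lam2 + 1e-300
    degenerate = (
        abs(ka - lam1) <= _DEGENERACY_RTOL * scale
        or abs(ka - lam2) <= _DEGENERACY_RTOL * scale
        or abs(lam1 - lam2) <= _DEGENERACY_RTOL * scale
        or k12 <= _DEGENERACY_RTOL * scale  # Q ~ 0: disposition eigenvectors collapse
    )
    if degenerate:
        return _MatexpPropagator(p.rate_matrix())

    det0 = (ka - lam1) * (ka - lam2)
    vc = -ka * (ka - k21) / det0
    vp = ka * k12 / det0
    V = np.array(
        [
            [1.0, 0.0, 0.0],
            [vc, k21 - lam1, k21 - lam2],
            [vp, k12, k12],
        ]
    )
    detW = k12 * (lam2 - lam1)
    Winv = np.array([[k12, -(k21 - lam2)], [-k12, k21 - lam1]]) / detW
    head = -Winv @ np.array([vc, vp])
    Vinv = np.array(
        [
            [1.0, 0.0, 0.0],
            [head[0], Winv[0, 0], Winv[0, 1]],
            [head[1], Winv[1, 0], Winv[1, 1]],
        ]
    )
    return _EigenPropagator(np.array([ka, lam1, lam2]), V, Vinv)


_PROPAGATOR_CACHE: dict[object, object] = {}


def _propagator(p):
    prop = _PROPAGATOR_CACHE.get(p)
    if prop is None:
        prop = _build_propagator(p)
        if len(_PROPAGATOR_CACHE) > 4096:
            _PROPAGATOR_CACHE.clear()
        _PROPAGATOR_CACHE[p] = prop
    return prop


def advance_interval_analytic(
    u: np.ndarray,
    p: TwoCptParams | OneCptParams,
    dt: float,
    infusion: np.ndarray | None = None,
) -> np.ndarray:
    """Exact state after ``dt`` hours under constant zero-order inputs.

    ``infusion`` gives per-compartment input rates in mg/h.  Linear in
    ``(u, infusion)``; ``dt=0`` returns ``u`` unchanged.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("state vector must be finite")
    if not (dt >= 0 and math.isfinite(dt)):
        raise ValueError(f"dt must be finite and >= 0, got {dt}")
    if u.shape != (p.n_cmt,):
        raise ValueError(f"state has {u.shape[0]} entries, model expects {p.n_cmt}")
    if infusion is not None:
        infusion = np.asarray(infusion, dtype=float)
        if not np.all(np.isfinite(infusion)):
            raise ValueError("infusion rates must be finite")
    return _propagator(p).advance(u, dt, infusion)


def matrix_exponential_advance(
    A: np.ndarray,
    u: np.ndarray,
    dt: float,
    b: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate ``du/dt = A u + b`` exactly over ``dt``.

    The constant-input particular solution is obtained from the exponential
    of the augmented matrix ``[[A, b], [0, 0]]``, so ``A`` need not be
    invertible.  The exponential itself is computed by scipy's
    scaling-and-squaring Pade routine.
    """
    A = np.asarray(A, dtype=float)
    u = np.asarray(u, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("A must be square")
    if u.shape != (n,):
        raise ValueError(f"state dimension {u.shape} does not match A ({n}x{n})")
    if dt == 0:
        return u.copy()
    if b is None or not np.any(b):
        return expm(A * dt) @ u
    b = np.asarray(b, dtype=float)
    if b.shape != (n,):
        raise ValueError("input vector b must match the state dimension")
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    E = expm(M * dt)
    return E[:n, :n] @ u + E[:n, n]


def steady_state_state(
    p_or_A,
    amt: float,
    rate: float,
    ii: float,
    cmt: int,
    F: float = 1.0,
) -> np.ndarray:
    """Periodic steady state of a repeated dosing regimen.

    For a bolus of ``F*amt`` mg into 1-based compartment ``cmt`` every
    ``ii`` hours, returns the post-dose fixed point ``u*`` solving
    ``u* = exp(A ii) u* + F amt e_cmt``.  For an infusion (``rate > 0``)
    the zero-order segment of duration ``F*amt/rate`` is handled inside
    the interval and the returned state is the one at the dose event time
    (infusion onset).  Requires strictly dissipative dynamics; a
    conservative system (e.g. CL = 0) has no steady state.
    """
    A = p_or_A.rate_matrix() if hasattr(p_or_A, "rate_matrix") else np.asarray(p_or_A, float)
    n = A.shape[0]
    if not 1 <= cmt <= n:
        raise EventValidationError(f"cmt={cmt} outside 1..{n}")
    if rate == 0 and not ii > 0:
        raise SolverError("steady-state bolus dosing requires ii > 0")
    scale = max(1.0, float(np.max(np.abs(A))))
    if np.max(np.linalg.eigvals(A).real) > -1e-12 * scale:
        raise SolverError("no steady state: system is not strictly dissipative")
    dose = F * amt
    e = np.zeros(n)
    e[cmt - 1] = dose
    eye = np.eye(n)
    if rate == 0:
        if math.isinf(ii):
            return e.copy()
        Phi = expm(A * ii)
        return np.linalg.solve(eye - Phi, e)
    if amt <= 0:
        raise SolverError("steady-state infusion requires amt > 0")
    tinf = dose / rate
    if math.isinf(ii):
        return np.zeros(n)
    if tinf > ii:
        raise SolverError(
            f"infusion duration {tinf:g} h exceeds the interdose interval {ii:g} h; "
            "overlapping steady-state infusions are not supported"
        )
    b = np.zeros(n)
    b[cmt - 1] = rate
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    E = expm(M * tinf)
    Phi1, q = E[:n, :n], E[:n, n]
    Phi2 = expm(A * (ii - tinf))
    return np.linalg.solve(eye - Phi2 @ Phi1, Phi2 @ q)


@dataclass
class SolutionMatrix:
    """Drug amount (mg) in every compartment at every event of a schedule.

    ``amounts`` has shape (n_cmt, n_events); column j is the state at event
    j's time (post-dose on dose rows).
    """

    amounts: np.ndarray
    schedule: EventSchedule

    @property
    def n_cmt(self) -> int:
        return self.amounts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Events as rows with source columns prepended and A1..An appended."""
        frame = to_frame(self.schedule)
        for i in range(self.n_cmt):
            frame[f"A{i + 1}"] = self.amounts[i]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def execute_plan(
    schedule: EventSchedule,
    n_cmt: int,
    advance: Callable[[np.ndarray, float, float, np.ndarray, int], np.ndarray],
    ss_state: Callable[[object, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Walk every subject's solve plan with a pluggable propagator.

    ``advance(u, t0, t1, infusion_rates, theta_index)`` integrates the
    state over a segment; ``ss_state(action, theta_index)`` returns the
    post-dose periodic steady state for an ss=1 dose row.  This single
    walker fixes the dosing semantics shared by the analytic, numeric and
    coupled solvers.
    """
    amounts = np.zeros((n_cmt, schedule.n_events))
    for sid in schedule.subjects:
        actions = event_grid(schedule, sid)
        u = np.zeros(n_cmt)
        inf = np.zeros(n_cmt)
        t = actions[0].time if actions else 0.0
        for a in actions:
            if a.kind in ("bolus", "infusion_start", "infusion_end", "ss_init"):
                if a.state_index >= n_cmt:
                    raise EventValidationError(
                        f"dose targets compartment {a.state_index + 1} but the model "
                        f"has only {n_cmt} compartments"
                    )
            if a.time > t:
                u = advance(u, t, a.time, inf, a.theta_index)
                t = a.time
            if a.kind == "record":
                amounts[:, a.record_index] = u
            elif a.kind == "bolus":
                u = u.copy()
                u[a.state_index] += a.amount
            elif a.kind == "infusion_start":
                inf = inf.copy()
                inf[a.state_index] += a.rate
            elif a.kind == "infusion_end":
                inf = inf.copy()
                inf[a.state_index] -= a.rate
            elif a.kind == "ss_init":
                if ss_state is None:
                    raise NotImplementedError(
                        "steady-state dosing (ss=1) is not supported by this solver"
                    )
                u = ss_state(a, a.theta_index)
    return amounts


def _as_theta_list(theta, n_events: int) -> Sequence:
    if isinstance(theta, (TwoCptParams, OneCptParams)):
        return [theta] * n_events
    theta = list(theta)
    if len(theta) == 1:
        return theta * n_events
    if len(theta) != n_events:
        raise ValueError(
            f"theta must have length 1 or n_events={n_events}, got {len(theta)}"
        )
    return theta


def solve_schedule_analytic(
    schedule: EventSchedule,
    theta,
    model: str = "twocpt",
) -> SolutionMatrix:
    """Closed-form solution of a (expanded) schedule.

    ``theta`` is a single parameter set or one per event; the set attached
    to an event governs the segment ending at that event.  ss=1 dose rows
    re-initialize the state from :func:`steady_state_state`.
    """
    if model not in ("twocpt", "onecpt"):
        raise ValueError(f"unknown model {model!r}")
    thetas = _as_theta_list(theta, schedule.n_events)
    expected = TwoCptParams if model == "twocpt" else OneCptParams
    if not all(isinstance(p, expected) for p in thetas):
        raise TypeError(f"model {model!r} expects {expected.__name__} parameter sets")
    n_cmt = thetas[0].n_cmt

    def advance(u, t0, t1, inf, ti):
        return advance_interval_analytic(u, thetas[ti], t1 - t0, inf)

    def ss_state(action, ti):
        return steady_state_state(
            thetas[ti], action.amount, action.rate, action.ii, action.state_index + 1
        )

    amounts = execute_plan(schedule, n_cmt, advance, ss_state)
    return SolutionMatrix(amounts, schedule)
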