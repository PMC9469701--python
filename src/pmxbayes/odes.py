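"""Tolerance-controlled numerical integration over event schedules.

Two entry points share the dosing semantics of the analytic path (both
walk the same solve plan):

* :func:`solve_schedule_numeric` integrates an arbitrary user right-hand
  side between events with an adaptive embedded Runge-Kutta 4(5) pair.
* :func:`solve_schedule_coupled` exploits the one-way coupling of PK/PD
  systems: the linear PK sub-state is propagated by its closed form and
  made available to the PD right-hand side at every *internal* integrator
  time (a continuous-time evaluation, not a per-event zero-order hold),
  while only the PD states are integrated numerically.  This shrinks the
  numerical problem from ``nPK + nPD`` to ``nPD`` states.

Local error is controlled by ``rtol``/``atol``; integration aborts with an
explicit error once ``max_num_step`` internal steps are exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import RK45

from .events import EventSchedule, EventValidationError
from .solvers import (
    OneCptParams,
    SolutionMatrix,
    TwoCptParams,
    _propagator,
    execute_plan,
)

__all__ = [
    "OdeSettings",
    "OdeError",
    "integrate",
    "solve_schedule_numeric",
    "solve_schedule_coupled",
]


class OdeError(RuntimeError):
    """Raised when numerical integration fails."""


@dataclass(frozen=True)
class OdeSettings:
    """Integrator controls: relative/absolute tolerance and step budget.

    Defaults (rtol=1e-6, atol=1e-6, max_num_step=100000) suit mg-scale
    amounts and ANC-scale counts; both tolerances should be tightened or
    relaxed together according to the scale below which a state may be
    neglected.
    """

    rtol: float = 1e-6
    atol: float = 1e-6
    max_num_step: int = 100_000

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("rtol and atol must be > 0")
        if not self.max_num_step > 0:
            raise ValueError("max_num_step must be > 0")

    @classmethod
    def from_config(cls, config: dict) -> "OdeSettings":
        keys = {k: config[k] for k in ("rtol", "atol", "max_num_step") if k in config}
        return cls(**keys)


def integrate(
    rhs: Callable,
    y0: np.ndarray,
    t0: float,
    t1: float,
    settings: OdeSettings = OdeSettings(),
    args: tuple = (),
) -> np.ndarray:
    """Adaptive RK4(5) solution of ``dy/dt = rhs(t, y, *args)`` on [t0, t1]."""
    y0 = np.asarray(y0, dtype=float)
    if t1 < t0:
        raise ValueError(f"t1={t1} must be >= t0={t0}")
    if t1 == t0:
        return y0.copy()

    def f(t, y):
        dy = np.asarray(rhs(t, y, *args), dtype=float)
        if not np.all(np.isfinite(dy)):
            raise OdeError(
                f"non-finite derivative at t={t:.6g} for state {np.array2string(y, precision=6)}"
            )
        return dy

    stepper = RK45(f, t0, y0, t_bound=t1, rtol=settings.rtol, atol=settings.atol)
    steps = 0
    while stepper.status == "running":
        if steps >= settings.max_num_step:
            raise OdeError(
                f"integration from t={t0:g} to t={t1:g} exceeded "
                f"max_num_step={settings.max_num_step} internal steps"
            )
        msg = stepper.step()
        steps += 1
        if stepper.status == "failed":
            raise OdeError(f"integrator failed at t={stepper.t:.6g}: {msg}")
    return stepper.y


def solve_schedule_numeric(
    schedule: EventSchedule,
    rhs: Callable,
    n_cmt: int,
    params=None,
    F: np.ndarray | None = None,
    tlag: np.ndarray | None = None,
    settings: OdeSettings = OdeSettings(),
) -> SolutionMatrix:
    """Numerical solution of an arbitrary right-hand side over a schedule.

    ``rhs(t, y, params)`` returns dy/dt for the ``n_cmt`` states.  Doses,
    bioavailability and lag times are applied exactly as in the analytic
    path; active infusions contribute a constant input vector added to the
    right-hand side.  Setting F=1 and tlag=0 for every compartment is
    identical to omitting them.  Steady-state rows are not supported on an
    arbitrary rhs (they would need a root find over the period map).
    """
    sched = schedule
    if F is not None or tlag is not None:
        sched = EventSchedule(
            schedule.records,
            F=F if F is not None else schedule.F,
            tlag=tlag if tlag is not None else schedule.tlag,
        )

    def advance(u, t0, t1, inf, ti):
        if np.any(inf):
            inf_const = inf.copy()

            def f(t, y, p):
                return np.asarray(rhs(t, y, p), dtype=float) + inf_const

        else:
            f = rhs
        try:
            return integrate(f, u, t0, t1, settings, args=(params,))
        except OdeError as err:
            raise OdeError(f"{err} (while advancing to event index {ti})") from err

    amounts = execute_plan(sched, n_cmt, advance, ss_state=None)
    return SolutionMatrix(amounts, sched)


def solve_schedule_coupled(
    schedule: EventSchedule,
    pk: TwoCptParams | OneCptParams,
    pd_rhs: Callable,
    n_pd: int,
    settings: OdeSettings = OdeSettings(),
    pd_params=None,
) -> SolutionMatrix:
    """One-way coupled PK/PD solve: closed-form PK, numerical PD.

    All doses must target PK compartments; the PD states receive none and
    start at zero (baseline-shifted coordinates).  ``pd_rhs(t, y_pd, y_pk,
    pd_params)`` sees the exact PK state at each internal integrator time.
    The output stacks the PK rows above the PD rows per event.
    """
    n_pk = pk.n_cmt
    prop = _propagator(pk)
    n_tot = n_pk + n_pd

    def advance(u, t0, t1, inf, ti):
        if np.any(inf[n_pk:]):
            raise EventValidationError("infusions may not target PD compartments")
        u_pk0 = u[:n_pk].copy()
        inf_pk = inf[:n_pk].copy()

        def f(t, y_pd, _):
            y_pk = prop.advance(u_pk0, t - t0, inf_pk)
            return np.asarray(pd_rhs(t, y_pd, y_pk, pd_params), dtype=float)

        y_pd = integrate(f, u[n_pk:], t0, t1, settings, args=(None,))
        out = np.empty(n_tot)
        out[:n_pk] = prop.advance(u_pk0, t1 - t0, inf_pk)
        out[n_pk:] = y_pd
        return out

    def ss_state(action, ti):
        if action.state_index >= n_pk:
            raise EventValidationError("doses may not target PD compartments")
        from .solvers import steady_state_state

        u = np.zeros(n_tot)
        u[:n_pk] = steady_state_state(
            pk, action.amount, action.rate, action.ii, action.state_index + 1
        )
        return u

    # doses into PD compartments are a contract violation, not a model choice
    for sid in schedule.subjects:
        for rec in schedule.subject_records(sid):
            if rec.is_dose and rec.cmt > n_pk:
                raise EventValidationError(
                    f"dose into compartment {rec.cmt} targets a PD state "
                    f"(PK has {n_pk} compartments)"
                )

    amounts = execute_plan(schedule, n_tot, advance, ss_state)
    return SolutionMatrix(amounts, schedule)
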