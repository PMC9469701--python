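"""Seeded synthetic data emulating the tutorial study designs.

The reference design is a multiple-dose plasma-concentration study in a
single individual: 1200 mg oral boluses every 12 h for 14 doses, with
rich sampling (12 timepoints over 8 h) after the first, second and final
doses, a predose sample before every dose, and follow-up samples 12, 18
and 24 h after the last dose — 53 measurement rows in all, the last at
180 h.

Residual error is lognormal; inter-individual variability is lognormal
with diagonal covariance around the population-typical values, with
allometric body-weight scaling of clearances and volumes.  The predose
sample at time zero has model concentration exactly zero (nothing has
been absorbed yet), which a lognormal error model cannot score, so
simulated datasets leave its dv missing; likelihood builders use only
rows with a recorded dv.

All randomness flows through a counter-based Philox generator keyed by
the caller's seed, so any dataset can be replayed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import EventRecord, EventSchedule, expand_additional_doses
from .models import allometric_params
from .posterior import _params_from_values, observed_rows  # noqa: F401
from .solvers import OneCptParams, TwoCptParams, solve_schedule_analytic

__all__ = [
    "RegimenSpec",
    "TUTORIAL_SAMPLING_TIMES",
    "build_tutorial_regimen",
    "simulate_dataset",
    "simulate_population",
    "rng_for",
]

#: post-dose sampling offsets (h) used after the densely observed doses
TUTORIAL_SAMPLING_TIMES = (0.083, 0.167, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)


def rng_for(seed: int) -> np.random.Generator:
    """Counter-based (Philox) generator so streams are replayable."""
    return np.random.Generator(np.random.Philox(key=np.uint64(seed)))


@dataclass(frozen=True)
class RegimenSpec:
    """A repeated-dose design with relative and absolute sampling times.

    ``dense_obs_doses`` lists 1-based dose numbers after which
    ``post_dose_times`` are sampled; ``predose`` adds a sample just before
    every dose; ``final_obs_times`` are offsets after the last dose.
    """

    amount: float = 1200.0
    ii: float = 12.0
    n_doses: int = 14
    cmt: int = 1
    rate: float = 0.0
    post_dose_times: tuple = TUTORIAL_SAMPLING_TIMES
    dense_obs_doses: tuple = (1, 2, 14)
    predose: bool = True
    final_obs_times: tuple = (12.0, 18.0, 24.0)
    obs_cmt: int = 2

    def compile(self, subject: str = "1") -> EventSchedule:
        """Expand to a time-sorted schedule (one dose row with addl)."""
        rows: list[tuple[float, int, EventRecord]] = []
        dose = EventRecord(
            id=subject, time=0.0, amt=self.amount, rate=self.rate, ii=self.ii,
            addl=self.n_doses - 1, cmt=self.cmt, evid=1,
        )
        obs_times: list[float] = []
        for d in self.dense_obs_doses:
            start = (d - 1) * self.ii
            obs_times.extend(start + t for t in self.post_dose_times)
        if self.predose:
            obs_times.extend(d * self.ii for d in range(self.n_doses))
        last = (self.n_doses - 1) * self.ii
        obs_times.extend(last + t for t in self.final_obs_times)
        # observations listed before the dose at shared times (predose reads)
        rows = [(t, 0, EventRecord(id=subject, time=t, cmt=self.obs_cmt, evid=0))
                for t in sorted(obs_times)]
        rows.append((0.0, 1, dose))
        rows.sort(key=lambda r: (r[0], r[1]))
        return EventSchedule([r[2] for r in rows])


def build_tutorial_regimen(subject: str = "1", expanded: bool = False) -> EventSchedule:
    """The reference single-subject design (53 observation rows).

    With ``expanded=True`` the 14 dose events are materialized (addl
    resolved), giving 67 rows ending at 180 h.
    """
    sched = RegimenSpec().compile(subject)
    return expand_additional_doses(sched) if expanded else sched


def simulate_dataset(
    schedule: EventSchedule,
    params: TwoCptParams | OneCptParams | dict,
    sigma: float,
    seed: int,
    model: str | None = None,
) -> EventSchedule:
    """Fill dv at observation rows with lognormal-noise measurements.

    ``dv = c_hat * exp(sigma * z)`` with z standard normal; rows whose
    model concentration is zero keep a missing dv.  ``sigma=0`` returns
    the model concentrations exactly.
    """
    if isinstance(params, dict):
        model = model or ("twocpt" if "Q" in params else "onecpt")
        params = _params_from_values(params, model)
    else:
        model = "twocpt" if isinstance(params, TwoCptParams) else "onecpt"
    sched = expand_additional_doses(schedule)
    sol = solve_schedule_analytic(sched, params, model=model)
    rng = rng_for(seed)
    records = list(sched.records)
    for i, rec in enumerate(records):
        if rec.is_observation:
            chat = sol.amounts[params.central_index, i] / params.Vcent
            if chat > 0:
                noise = np.exp(sigma * rng.standard_normal()) if sigma > 0 else 1.0
                records[i] = replace(rec, dv=float(chat * noise))
    return EventSchedule(records, F=sched.F, tlag=sched.tlag)


def simulate_population(
    n_subjects: int,
    theta_pop: dict,
    omega: dict,
    weights,
    sigma: float,
    seed: int,
    regimen: RegimenSpec | None = None,
    ref_weight: float = 70.0,
    exp_clearance: float = 0.75,
    exp_volume: float = 1.0,
) -> EventSchedule:
    """Multi-subject dataset from the lognormal population model.

    Per subject j: draw normalized parameters lognormally around
    ``theta_pop`` with log-scale sd ``omega`` (omega=0 collapses to the
    typical values), scale allometrically by the subject's body weight,
    solve the regimen and add lognormal residual noise.  Body weight is
    attached to every record as the ``wt`` covariate.
    """
    regimen = regimen or RegimenSpec()
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_subjects,):
        raise ValueError(f"need {n_subjects} body weights, got {weights.shape}")
    rng = rng_for(seed)
    names = list(theta_pop)
    records: list[EventRecord] = []
    for j in range(n_subjects):
        sid = str(j + 1)
        draws = {
            k: float(theta_pop[k] * np.exp(omega[k] * rng.standard_normal()))
            if omega[k] > 0
            else float(theta_pop[k])
            for k in names
        }
        norm = TwoCptParams(**draws)
        p = allometric_params(norm, weights[j], exp_clearance, exp_volume, ref_weight)
        sub = regimen.compile(sid)
        sub_data = simulate_dataset(sub, p, sigma, seed=int(rng.integers(2**31)))
        for rec in sub_data.records:
            covs = dict(rec.covariates)
            covs["wt"] = float(weights[j])
            records.append(replace(rec, covariates=covs))
    return EventSchedule(records)
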