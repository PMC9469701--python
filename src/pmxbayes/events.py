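"""Clinical event schedules.

Dosing and measurement events follow the NONMEM data conventions: one row
per event carrying ``time``, ``amt``, ``rate``, ``ii``, ``addl``, ``cmt``,
``evid``, ``ss`` and, for measurement rows, the observed value ``dv``.
An :class:`EventSchedule` is the single input contract for every solver in
this package: the schedule is compiled to a chronological *solve plan*
(:func:`event_grid`) that interleaves integration segments with dose
actions and state recordings.

Only ``evid`` codes 0 (measurement) and 1 (dose) are defined here; reset
codes are rejected rather than silently ignored.  Compartment indices are
1-based in tables (``cmt``) and converted to 0-based state indices inside
this module only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "EventSchedule",
    "GridAction",
    "read_events_table",
    "read_events_csv",
    "write_events_csv",
    "to_frame",
    "expand_additional_doses",
    "event_grid",
    "observation_view",
]

#: canonical column order for event tables
EVENT_COLUMNS = ("id", "time", "amt", "rate", "ii", "addl", "cmt", "evid", "ss", "dv")


class EventValidationError(ValueError):
    """Raised when an event row violates the schedule invariants."""


@dataclass(frozen=True)
class EventRecord:
    """One clinical event: a dose (evid=1) or a measurement (evid=0).

    Units follow pharmacometric convention: ``time``/``ii`` in hours,
    ``amt`` in mg, ``rate`` in mg/h (0 means an instantaneous bolus),
    ``dv`` in the observation stream's units (mg/L for concentration).
    """

    time: float
    cmt: int
    evid: int
    id: str = "1"
    amt: float = 0.0
    rate: float = 0.0
    ii: float = 0.0
    addl: int = 0
    ss: int = 0
    dv: float | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evid not in (0, 1):
            raise EventValidationError(
                f"evid={self.evid!r} is not a defined event type: "
                "only 0 (measurement) and 1 (dosing) are supported; "
                "reset/reset-dose codes are out of contract"
            )
        if not (self.time >= 0 and math.isfinite(self.time)):
            raise EventValidationError(f"time must be finite and >= 0, got {self.time}")
        for name in ("amt", "rate", "ii"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise EventValidationError(f"{name} must be finite and >= 0, got {v}")
        if not (isinstance(self.addl, (int, np.integer)) and self.addl >= 0):
            raise EventValidationError(f"addl must be a non-negative integer, got {self.addl}")
        if self.ss not in (0, 1):
            raise EventValidationError(f"ss must be 0 or 1, got {self.ss}")
        if self.cmt < 1:
            raise EventValidationError(f"cmt is 1-based and must be >= 1, got {self.cmt}")
        if self.addl > 0:
            if self.ii <= 0:
                raise EventValidationError("addl > 0 requires ii > 0")
            if self.evid != 1:
                raise EventValidationError("addl > 0 requires a dosing event (evid=1)")
        if self.ss == 1:
            if self.evid != 1:
                raise EventValidationError("ss=1 requires a dosing event (evid=1)")
            if self.ii <= 0:
                raise EventValidationError("ss=1 requires ii > 0")
        if self.amt > 0 and self.evid != 1:
            raise EventValidationError("amt > 0 requires a dosing event (evid=1)")
        if self.evid == 1 and self.dv is not None:
            # dv is only defined on measurement rows
            object.__setattr__(self, "dv", None)

    @property
    def is_dose(self) -> bool:
        return self.evid == 1

    @property
    def is_observation(self) -> bool:
        return self.evid == 0


@dataclass
class EventSchedule:
    """An ordered event table grouped by subject.

    ``F`` and ``tlag`` are per-compartment bioavailability fractions and
    dose lag times (defaults 1 and 0); their length fixes the compartment
    count expected by a solver when set.
    """

    records: list[EventRecord]
    F: np.ndarray | None = None
    tlag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if self.F is not None:
            self.F = np.asarray(self.F, dtype=float)
            if np.any(self.F <= 0) or np.any(self.F > 1):
                raise EventValidationError("bioavailability fractions F must be in (0, 1]")
        if self.tlag is not None:
            self.tlag = np.asarray(self.tlag, dtype=float)
            if np.any(self.tlag < 0):
                raise EventValidationError("lag times tlag must be >= 0")
        # subjects must form contiguous blocks with non-decreasing times
        seen: dict[str, int] = {}
        order: list[str] = []
        for i, rec in enumerate(self.records):
            if rec.id in seen:
                j = seen[rec.id]
                if self.records[i - 1].id != rec.id:
                    raise EventValidationError(
                        f"subject {rec.id!r} appears in non-contiguous blocks"
                    )
                if rec.time < self.records[i - 1].time:
                    raise EventValidationError(
                        f"times for subject {rec.id!r} must be non-decreasing"
                    )
                seen[rec.id] = i
            else:
                seen[rec.id] = i
                order.append(rec.id)
        self._subject_order = order

    # -- structure ---------------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> list[str]:
        return list(self._subject_order)

    def subject_slice(self, subject: str) -> slice:
        """Index range (start, end) of one subject's contiguous block."""
        idx = [i for i, r in enumerate(self.records) if r.id == subject]
        if not idx:
            raise KeyError(f"unknown subject {subject!r}")
        return slice(idx[0], idx[-1] + 1)

    def subject_records(self, subject: str) -> list[EventRecord]:
        sl = self.subject_slice(subject)
        return self.records[sl]

    def f_for(self, cmt: int) -> float:
        """Bioavailability for a 1-based compartment index."""
        if self.F is None:
            return 1.0
        return float(self.F[cmt - 1])

    def tlag_for(self, cmt: int) -> float:
        if self.tlag is None:
            return 0.0
        return float(self.tlag[cmt - 1])

    def observation_view(self) -> dict[str, np.ndarray]:
        return observation_view(self)


def _parse_cell(value, default, caster):
    if value is None:
        return default
    if isinstance(value, str):
        v = value.strip()
        if v in ("", "."):
            return default
        return caster(float(v)) if caster is int else caster(v)
    if isinstance(value, float) and math.isnan(value):
        return default
    return caster(value)


def read_events_table(rows, F=None, tlag=None) -> EventSchedule:
    """Build an :class:`EventSchedule` from tabular records.

    ``rows`` may be a :class:`pandas.DataFrame` or an iterable of mappings.
    Columns ``time``, ``cmt`` and ``evid`` are required; ``amt``, ``rate``,
    ``ii``, ``addl`` and ``ss`` default to 0, ``id`` to ``"1"``.  Blank
    cells and ``"."`` are missing markers.  Any extra column (e.g. a body
    weight ``wt``) is kept as a per-record covariate.  Rows are grouped by
    subject in order of first appearance, preserving input order within
    each subject.
    """
    if isinstance(rows, pd.DataFrame):
        cols = [str(c).strip().lower() for c in rows.columns]
        frame = rows.copy()
        frame.columns = cols
        row_iter: Iterable[Mapping] = frame.to_dict(orient="records")
    else:
        row_iter = [{str(k).strip().lower(): v for k, v in r.items()} for r in rows]
        cols = sorted({k for r in row_iter for k in r})
    for required in ("time", "cmt", "evid"):
        if required not in cols:
            raise EventValidationError(f"required column {required!r} is missing")

    known = set(EVENT_COLUMNS)
    records = []
    for raw in row_iter:
        evid = _parse_cell(raw.get("evid"), None, int)
        if evid is None:
            raise EventValidationError("evid may not be missing")
        covs = {
            k: float(v)
            for k, v in raw.items()
            if k not in known and _parse_cell(v, None, float) is not None
        }
        rec = EventRecord(
            id=str(_parse_cell(raw.get("id"), "1", str)),
            time=_parse_cell(raw.get("time"), None, float),
            amt=_parse_cell(raw.get("amt"), 0.0, float),
            rate=_parse_cell(raw.get("rate"), 0.0, float),
            ii=_parse_cell(raw.get("ii"), 0.0, float),
            addl=_parse_cell(raw.get("addl"), 0, int),
            cmt=_parse_cell(raw.get("cmt"), None, int),
            evid=evid,
            ss=_parse_cell(raw.get("ss"), 0, int),
            dv=_parse_cell(raw.get("dv"), None, float),
            covariates=covs,
        )
        records.append(rec)

    # group by subject preserving first-appearance order and input order
    grouped: dict[str, list[EventRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.id, []).append(rec)
    ordered = [rec for sid in grouped for rec in grouped[sid]]
    return EventSchedule(ordered, F=F, tlag=tlag)


def read_events_csv(path: str | Path, **kwargs) -> EventSchedule:
    """Read an events CSV (UTF-8, ``"."`` accepted as missing marker)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    return read_events_table(frame, **kwargs)


def to_frame(schedule: EventSchedule) -> pd.DataFrame:
    """Canonical tabular form; missing dv written as the ``"."`` marker."""
    cov_names = sorted({k for r in schedule.records for k in r.covariates})
    rows = []
    for r in schedule.records:
        row = {
            "id": r.id,
            "time": r.time,
            "amt": r.amt,
            "rate": r.rate,
            "ii": r.ii,
            "addl": r.addl,
            "cmt": r.cmt,
            "evid": r.evid,
            "ss": r.ss,
            "dv": "." if r.dv is None else r.dv,
        }
        for c in cov_names:
            row[c] = r.covariates.get(c, ".")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS) + cov_names)


def write_events_csv(schedule: EventSchedule, path: str | Path) -> None:
    to_frame(schedule).to_csv(path, index=False, encoding="utf-8")


def expand_additional_doses(schedule: EventSchedule) -> EventSchedule:
    """Replace each dose row with ``addl=k > 0`` by ``k+1`` explicit doses.

    The copies sit at ``t, t+ii, ..., t+k*ii`` with ``addl=0``; a steady
    state flag applies to the first copy only (later copies propagate
    normally).  Observation rows are untouched.  Within each subject the
    result is re-sorted by time with a stable sort: records sharing a
    timestamp keep their input order, and generated copies (k >= 1) sort
    after same-time original records — so a trough observation recorded at
    a repeat-dose time reads the pre-dose state.  The operation is
    idempotent and conserves total administered mass: sum(amt) after =
    sum(amt*(addl+1)) before.
    """
    out: list[EventRecord] = []
    for sid in schedule.subjects:
        expanded: list[tuple[int, EventRecord]] = []  # (generated flag, record)
        for rec in schedule.subject_records(sid):
            if rec.is_dose and rec.addl > 0:
                for k in range(rec.addl + 1):
                    expanded.append(
                        (
                            int(k > 0),
                            replace(
                                rec,
                                time=rec.time + k * rec.ii,
                                addl=0,
                                ii=rec.ii,
                                ss=rec.ss if k == 0 else 0,
                            ),
                        )
                    )
            else:
                expanded.append((0, rec))
        expanded.sort(key=lambda pair: (pair[1].time, pair[0]))
        out.extend(rec for _, rec in expanded)
    return EventSchedule(out, F=schedule.F, tlag=schedule.tlag)


def observation_view(schedule: EventSchedule) -> dict[str, np.ndarray]:
    """Global indices of measurement rows (evid=0), per subject, in order."""
    view: dict[str, np.ndarray] = {}
    for sid in schedule.subjects:
        sl = schedule.subject_slice(sid)
        view[sid] = np.array(
            [i for i in range(sl.start, sl.stop) if schedule.records[i].is_observation],
            dtype=int,
        )
    return view


@dataclass(frozen=True)
class GridAction:
    """One step of a solve plan.

    ``kind`` is one of ``"record"`` (store the state for event
    ``record_index``), ``"bolus"`` (add ``amount`` mg to 0-based state
    index ``state_index``), ``"infusion_start"``/``"infusion_end"``
    (toggle a zero-order input of ``rate`` mg/h), or ``"ss_init"``
    (re-initialize the state from the periodic steady state of the dosing
    regimen carried in ``amount``/``rate``/``ii``).  ``theta_index`` is
    the schedule-row index whose parameter set governs the segment ending
    at this action.
    """

    time: float
    seq: int
    kind: str
    state_index: int = 0
    amount: float = 0.0
    rate: float = 0.0
    ii: float = 0.0
    record_index: int = -1
    theta_index: int = 0


def event_grid(schedule: EventSchedule, subject: str) -> list[GridAction]:
    """Compile one subject's events into a chronological solve plan.

    Requires additional doses to be expanded first.  Dose actions are
    lag-shifted by ``tlag[cmt]``; an infusion of amount ``amt`` at rate
    ``rate`` delivers ``F*amt`` over a duration ``F*amt/rate``.  Actions
    sharing a timestamp execute in input-record order (a dose row records
    the post-dose state; an observation row listed before a same-time dose
    reads the pre-dose state).  The plan is deterministic: rebuilding from
    the same schedule yields an identical plan.
    """
    sl = schedule.subject_slice(subject)
    actions: list[GridAction] = []
    seq = 0
    for idx in range(sl.start, sl.stop):
        rec = schedule.records[idx]
        if rec.addl > 0:
            raise EventValidationError(
                "event_grid requires expanded schedules; call expand_additional_doses first"
            )
        if rec.is_dose:
            f = schedule.f_for(rec.cmt)
            lag = schedule.tlag_for(rec.cmt)
            t_apply = rec.time + lag
            if rec.ss == 1:
                actions.append(
                    GridAction(
                        time=rec.time,
                        seq=seq,
                        kind="ss_init",
                        state_index=rec.cmt - 1,
                        amount=rec.amt * f,
                        rate=rec.rate,
                        ii=rec.ii,
                        theta_index=idx,
                    )
                )
                seq += 1
            elif rec.rate > 0:
                if rec.amt <= 0:
                    raise EventValidationError(
                        "rate > 0 with amt = 0 leaves the infusion duration undefined"
                    )
                duration = f * rec.amt / rec.rate
                actions.append(
                    GridAction(
                        time=t_apply,
                        seq=seq,
                        kind="infusion_start",
                        state_index=rec.cmt - 1,
                        rate=rec.rate,
                        theta_index=idx,
                    )
                )
                seq += 1
                actions.append(
                    GridAction(
                        time=t_apply + duration,
                        seq=seq,
                        kind="infusion_end",
                        state_index=rec.cmt - 1,
                        rate=rec.rate,
                        theta_index=idx,
                    )
                )
                seq += 1
            elif rec.amt > 0:
                actions.append(
                    GridAction(
                        time=t_apply,
                        seq=seq,
                        kind="bolus",
                        state_index=rec.cmt - 1,
                        amount=rec.amt * f,
                        theta_index=idx,
                    )
                )
                seq += 1
        actions.append(
            GridAction(
                time=rec.time,
                seq=seq,
                kind="record",
                record_index=idx,
                theta_index=idx,
            )
        )
        seq += 1
    actions.sort(key=lambda a: a.time)  # stable: seq order preserved at ties
    return actions
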