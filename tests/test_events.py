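"""Event-table parsing, dose expansion, solve plans, and round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmxbayes.events import (
    EventRecord,
    EventSchedule,
    EventValidationError,
    event_grid,
    expand_additional_doses,
    observation_view,
    read_events_table,
    to_frame,
)


def make_schedule(rows, **kw):
    return read_events_table(pd.DataFrame(rows), **kw)


class TestReadEventsTable:
    def test_missing_fields_default_to_zero(self):
        sched = make_schedule([dict(time=0, amt=1200, cmt=1, evid=1)])
        rec = sched.records[0]
        assert (rec.rate, rec.ii, rec.addl, rec.ss) == (0.0, 0.0, 0, 0)
        assert rec.dv is None

    def test_repeated_dosing_fields_are_preserved(self):
        sched = make_schedule([dict(time=0, amt=1200, cmt=1, evid=1, ii=12, addl=13)])
        assert sched.records[0].addl == 13
        assert sched.records[0].ii == 12.0

    @pytest.mark.parametrize(
        "row, match",
        [
            (dict(time=1, cmt=1, evid=2), "evid"),
            (dict(time=0, amt=10, cmt=1, evid=1, addl=2), "addl"),
            (dict(time=-1, cmt=1, evid=0), "time"),
            (dict(time=0, amt=-5, cmt=1, evid=1), "amt"),
            (dict(time=0, amt=10, cmt=1, evid=0), "evid"),
            (dict(time=0, amt=10, cmt=1, evid=1, ss=1), "ss"),
        ],
    )
    def test_contract_violations_are_rejected(self, row, match):
        with pytest.raises(EventValidationError, match=match):
            make_schedule([row])

    def test_dot_is_accepted_as_missing_marker(self):
        sched = make_schedule(
            [dict(id="1", time="0", amt="1200", rate=".", ii=".", cmt="1", evid="1", dv=".")]
        )
        assert sched.records[0].rate == 0.0

    def test_extra_columns_become_covariates(self):
        sched = make_schedule([dict(time=0, cmt=2, evid=0, wt=82.5)])
        assert sched.records[0].covariates["wt"] == 82.5

    def test_subjects_grouped_by_first_appearance(self):
        sched = make_schedule(
            [
                dict(id="b", time=0, cmt=2, evid=0),
                dict(id="a", time=0, cmt=2, evid=0),
                dict(id="b", time=1, cmt=2, evid=0),
            ]
        )
        assert sched.subjects == ["b", "a"]
        assert sched.subject_slice("b") == slice(0, 2)

    def test_round_trip_through_frame_is_identical(self):
        rows = [
            dict(id="1", time=0.0, amt=1200.0, cmt=1, evid=1, ii=12.0, addl=3),
            dict(id="1", time=1.5, cmt=2, evid=0, dv=4.25),
            dict(id="2", time=0.0, amt=600.0, rate=300.0, cmt=1, evid=1),
        ]
        first = make_schedule(rows)
        second = read_events_table(to_frame(first))
        assert to_frame(first).equals(to_frame(second))
        assert first.records == second.records


class TestExpandAdditionalDoses:
    def test_fourteen_q12h_doses_from_one_row(self):
        sched = make_schedule([dict(time=0, amt=1200, cmt=1, evid=1, ii=12, addl=13)])
        ex = expand_additional_doses(sched)
        assert ex.n_events == 14
        assert [r.time for r in ex.records] == [12.0 * k for k in range(14)]
        assert all(r.addl == 0 for r in ex.records)

    def test_no_addl_is_identity(self):
        sched = make_schedule(
            [dict(time=0, amt=100, cmt=1, evid=1), dict(time=2, cmt=2, evid=0)]
        )
        assert expand_additional_doses(sched).records == sched.records

    def test_small_expansion_enumerates_every_interval(self):
        sched = make_schedule([dict(time=0, amt=10, cmt=1, evid=1, ii=6, addl=2)])
        times = [r.time for r in expand_additional_doses(sched).records]
        assert times == [0.0, 6.0, 12.0]

    def test_expansion_is_idempotent(self):
        sched = make_schedule([dict(time=0, amt=10, cmt=1, evid=1, ii=6, addl=4)])
        once = expand_additional_doses(sched)
        twice = expand_additional_doses(once)
        assert once.records == twice.records

    def test_generated_doses_sort_after_same_time_observations(self):
        sched = make_schedule(
            [
                dict(time=0, amt=10, cmt=1, evid=1, ii=12, addl=1),
                dict(time=12, cmt=2, evid=0),
            ]
        )
        ex = expand_additional_doses(sched)
        kinds = [(r.time, r.evid) for r in ex.records]
        assert kinds == [(0.0, 1), (12.0, 0), (12.0, 1)]

    def test_steady_state_applies_to_first_copy_only(self):
        sched = make_schedule([dict(time=0, amt=10, cmt=1, evid=1, ii=8, addl=2, ss=1)])
        ex = expand_additional_doses(sched)
        assert [r.ss for r in ex.records] == [1, 0, 0]

    @given(
        amt=st.floats(0.1, 1e4),
        ii=st.floats(0.5, 48.0),
        addl=st.integers(0, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_administered_mass_is_conserved(self, amt, ii, addl):
        sched = make_schedule([dict(time=0, amt=amt, cmt=1, evid=1, ii=ii, addl=addl)])
        ex = expand_additional_doses(sched)
        total = sum(r.amt for r in ex.records if r.is_dose)
        assert total == pytest.approx(amt * (addl + 1), rel=1e-12)


class TestEventGrid:
    def test_dose_action_precedes_its_own_record(self):
        sched = make_schedule(
            [dict(time=0, amt=100, cmt=1, evid=1), dict(time=0, cmt=2, evid=0)]
        )
        plan = event_grid(sched, "1")
        kinds = [a.kind for a in plan]
        assert kinds == ["bolus", "record", "record"]

    def test_observation_listed_before_dose_reads_predose_state(self):
        sched = make_schedule(
            [dict(time=0, cmt=2, evid=0), dict(time=0, amt=100, cmt=1, evid=1)]
        )
        kinds = [a.kind for a in event_grid(sched, "1")]
        assert kinds == ["record", "bolus", "record"]

    def test_infusion_duration_is_amount_over_rate(self):
        sched = make_schedule([dict(time=0, amt=1200, rate=300, cmt=1, evid=1)])
        plan = event_grid(sched, "1")
        start = next(a for a in plan if a.kind == "infusion_start")
        end = next(a for a in plan if a.kind == "infusion_end")
        assert (start.time, end.time) == (0.0, 4.0)

    def test_lag_shifts_the_dose_entry_time_only(self):
        sched = make_schedule(
            [dict(time=0, amt=100, cmt=1, evid=1), dict(time=2, cmt=2, evid=0)],
            tlag=[0.5, 0.0],
        )
        plan = event_grid(sched, "1")
        bolus = next(a for a in plan if a.kind == "bolus")
        assert bolus.time == 0.5
        # the dose row itself still records at the nominal time
        assert [a.time for a in plan if a.kind == "record"] == [0.0, 2.0]

    def test_rate_without_amount_is_rejected(self):
        with pytest.raises(EventValidationError, match="rate"):
            sched = EventSchedule(
                [EventRecord(time=0.0, cmt=1, evid=1, amt=0.0, rate=10.0)]
            )
            event_grid(sched, "1")

    def test_unexpanded_schedule_is_rejected(self):
        sched = make_schedule([dict(time=0, amt=10, cmt=1, evid=1, ii=6, addl=2)])
        with pytest.raises(EventValidationError, match="expand"):
            event_grid(sched, "1")

    def test_plan_is_deterministic(self):
        sched = make_schedule(
            [
                dict(time=0, amt=100, cmt=1, evid=1),
                dict(time=0, cmt=2, evid=0),
                dict(time=4, amt=50, rate=25, cmt=1, evid=1),
                dict(time=6, cmt=2, evid=0),
            ]
        )
        assert event_grid(sched, "1") == event_grid(sched, "1")


class TestObservationView:
    def test_no_measurement_rows_gives_empty_view(self):
        sched = make_schedule([dict(time=0, amt=10, cmt=1, evid=1)])
        assert observation_view(sched)["1"].size == 0

    def test_tutorial_design_has_53_observation_rows(self, expanded_schedule):
        view = observation_view(expanded_schedule)
        assert view["1"].size == 53
        assert expanded_schedule.n_events == 67
        assert max(r.time for r in expanded_schedule.records) == 180.0

    def test_dose_rows_never_appear_in_the_view(self, expanded_schedule):
        view = observation_view(expanded_schedule)
        assert all(
            expanded_schedule.records[i].is_observation for i in view["1"]
        )
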