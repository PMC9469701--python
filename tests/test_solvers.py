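"""Closed-form solvers against matrix-exponential and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from pmxbayes.events import read_events_table, expand_additional_doses
from pmxbayes.solvers import (
    OneCptParams,
    SolverError,
    TwoCptParams,
    advance_interval_analytic,
    hybrid_constants,
    matrix_exponential_advance,
    solve_schedule_analytic,
    steady_state_state,
)
from pmxbayes import fastpath

positive = st.floats(0.05, 200.0)
params_st = st.builds(
    TwoCptParams, CL=positive, Q=positive, Vcent=positive, Vperi=positive, ka=positive
)


class TestHybridConstants:
    @given(p=params_st)
    @settings(max_examples=100, deadline=None)
    def test_vieta_identities(self, p):
        k10, k12, k21, l1, l2 = hybrid_constants(p)
        assert l1 * l2 == pytest.approx(k10 * k21, rel=1e-12)
        assert l1 + l2 == pytest.approx(k10 + k12 + k21, rel=1e-12)
        assert l1 >= l2 >= 0

    def test_decoupled_limit_without_intercompartmental_flow(self):
        p = TwoCptParams(CL=10, Q=0.0, Vcent=20, Vperi=50, ka=1.0)
        k10, _, _, l1, l2 = hybrid_constants(p)
        assert l1 == pytest.approx(k10)
        assert l2 == pytest.approx(0.0, abs=1e-15)

    def test_reference_parameter_set(self):
        # quadratic-root oracle: np.roots on the characteristic polynomial
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        k10, k12, k21, l1, l2 = hybrid_constants(p)
        roots = np.sort(np.roots([1.0, -(k10 + k12 + k21), k10 * k21]))[::-1]
        assert l1 == pytest.approx(roots[0], rel=1e-12)
        assert l2 == pytest.approx(roots[1], rel=1e-12)
        assert l1 == pytest.approx(0.8065, abs=5e-5)
        assert l2 == pytest.approx(0.0506, abs=5e-5)

    def test_rejects_nonpositive_volumes(self):
        with pytest.raises(ValueError):
            TwoCptParams(CL=1, Q=1, Vcent=0.0, Vperi=1, ka=1)


class TestAdvanceIntervalAnalytic:
    def test_zero_interval_is_identity(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        u = np.array([100.0, 50.0, 25.0])
        assert advance_interval_analytic(u, p, 0.0) == pytest.approx(u)

    def test_absorption_only_closed_form(self):
        # CL = Q = 0: gut decays exp(-ka t), everything lands in central
        p = TwoCptParams(CL=0.0, Q=0.0, Vcent=35, Vperi=105, ka=0.7)
        u = advance_interval_analytic(np.array([200.0, 0.0, 0.0]), p, 3.0)
        assert u[0] == pytest.approx(200 * np.exp(-0.7 * 3.0), rel=1e-10)
        assert u[1] == pytest.approx(200 * (1 - np.exp(-0.7 * 3.0)), rel=1e-10)
        assert u.sum() == pytest.approx(200.0, rel=1e-10)

    @given(
        p=params_st,
        dt=st.floats(0.0, 48.0),
        gut=st.floats(0, 1e3),
        cen=st.floats(0, 1e3),
        per=st.floats(0, 1e3),
        rate=st.floats(0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_matrix_exponential_oracle(self, p, dt, gut, cen, per, rate):
        u = np.array([gut, cen, per])
        inf = np.array([rate, 0.0, 0.0])
        got = advance_interval_analytic(u, p, dt, inf)
        want = matrix_exponential_advance(p.rate_matrix(), u, dt, inf)
        scale = max(1.0, np.max(np.abs(want)))
        assert np.max(np.abs(got - want)) / scale < 1e-10

    @given(p=params_st, dt1=st.floats(0.01, 24.0), dt2=st.floats(0.01, 24.0))
    @settings(max_examples=50, deadline=None)
    def test_semigroup_property(self, p, dt1, dt2):
        u = np.array([300.0, 40.0, 10.0])
        via = advance_interval_analytic(
            advance_interval_analytic(u, p, dt1), p, dt2
        )
        direct = advance_interval_analytic(u, p, dt1 + dt2)
        scale = max(1.0, np.max(np.abs(direct)))
        assert np.max(np.abs(via - direct)) / scale < 1e-10

    def test_mass_conserved_without_elimination(self):
        p = TwoCptParams(CL=0.0, Q=12.0, Vcent=30, Vperi=60, ka=1.3)
        u = np.array([500.0, 100.0, 0.0])
        for dt in (0.5, 5.0, 50.0):
            u = advance_interval_analytic(u, p, dt)
        assert u.sum() == pytest.approx(600.0, rel=1e-10)

    def test_rejects_nonfinite_state(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        with pytest.raises(ValueError, match="finite"):
            advance_interval_analytic(np.array([np.nan, 0, 0]), p, 1.0)


class TestMatrixExponentialAdvance:
    def test_zero_interval_is_identity(self):
        A = np.array([[-0.3]])
        assert matrix_exponential_advance(A, np.array([5.0]), 0.0) == pytest.approx([5.0])

    def test_scalar_closed_form_with_constant_input(self):
        k, r, u0, dt = 0.4, 2.0, 7.0, 3.0
        got = matrix_exponential_advance(np.array([[-k]]), np.array([u0]), dt, np.array([r]))
        want = u0 * np.exp(-k * dt) + (r / k) * (1 - np.exp(-k * dt))
        assert got[0] == pytest.approx(want, rel=1e-12)

    def test_nilpotent_transit_chain_is_polynomial(self):
        # strictly lower-triangular A: series terminates, solution polynomial in dt
        A = np.zeros((3, 3))
        A[1, 0] = 2.0
        A[2, 1] = 3.0
        u0 = np.array([1.0, 0.0, 0.0])
        dt = 0.7
        got = matrix_exponential_advance(A, u0, dt)
        want = np.array([1.0, 2.0 * dt, 3.0 * 2.0 * dt**2 / 2.0])
        assert got == pytest.approx(want, rel=1e-12)

    def test_dimension_mismatch_is_rejected(self):
        with pytest.raises(ValueError):
            matrix_exponential_advance(np.eye(2), np.zeros(3), 1.0)


class TestSteadyState:
    def test_one_compartment_bolus_geometric_series(self):
        p = OneCptParams(CL=5.0, Vcent=20.0, ka=1.0)
        k10 = p.CL / p.Vcent
        amt, ii, F = 100.0, 12.0, 0.8
        u = steady_state_state(p, amt, 0.0, ii, cmt=2, F=F)
        assert u[1] == pytest.approx(F * amt / (1 - np.exp(-k10 * ii)), rel=1e-12)

    def test_infinite_interval_reduces_to_single_fresh_dose(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        u = steady_state_state(p, 1200.0, 0.0, np.inf, cmt=1)
        assert u == pytest.approx([1200.0, 0.0, 0.0])

    def test_matches_brute_force_repeated_dosing(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        uss = steady_state_state(p, 1200.0, 0.0, 12.0, cmt=1)
        u = np.zeros(3)
        for _ in range(100):  # long-run simulation oracle
            u = advance_interval_analytic(u, p, 12.0)
            u[0] += 1200.0
        assert np.max(np.abs(uss - u) / np.abs(u)) < 1e-8

    def test_infusion_steady_state_matches_brute_force(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        amt, rate, ii = 1200.0, 300.0, 12.0
        uss = steady_state_state(p, amt, rate, ii, cmt=2)
        u = np.zeros(3)
        inf = np.array([0.0, rate, 0.0])
        tinf = amt / rate
        for _ in range(100):
            u = advance_interval_analytic(u, p, tinf, inf)
            u = advance_interval_analytic(u, p, ii - tinf)
        assert np.max(np.abs(uss - u) / np.maximum(np.abs(u), 1e-12)) < 1e-8

    def test_fixed_point_property(self):
        p = TwoCptParams(CL=7, Q=11, Vcent=25, Vperi=80, ka=1.4)
        uss = steady_state_state(p, 500.0, 0.0, 24.0, cmt=1)
        u = advance_interval_analytic(uss, p, 24.0)
        u[0] += 500.0
        assert np.max(np.abs(u - uss) / np.maximum(np.abs(uss), 1e-12)) < 1e-10

    def test_conservative_system_has_no_steady_state(self):
        p = TwoCptParams(CL=0.0, Q=15, Vcent=35, Vperi=105, ka=2.0)
        with pytest.raises(SolverError, match="steady state"):
            steady_state_state(p, 100.0, 0.0, 12.0, cmt=1)


class TestSolveScheduleAnalytic:
    def test_single_bolus_recorded_post_dose(self):
        sched = read_events_table(
            pd.DataFrame(
                [dict(time=0, amt=1200, cmt=1, evid=1), dict(time=0, cmt=2, evid=0)]
            )
        )
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        sol = solve_schedule_analytic(sched, p)
        assert sol.amounts[:, 0] == pytest.approx([1200.0, 0.0, 0.0])
        assert sol.amounts[:, 1] == pytest.approx([1200.0, 0.0, 0.0])

    def test_linearity_in_dose(self, expanded_schedule):
        from dataclasses import replace

        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        base = solve_schedule_analytic(expanded_schedule, p)
        doubled_records = [
            replace(r, amt=2 * r.amt) if r.is_dose else r
            for r in expanded_schedule.records
        ]
        from pmxbayes.events import EventSchedule

        doubled = solve_schedule_analytic(EventSchedule(doubled_records), p)
        assert doubled.amounts == pytest.approx(2 * base.amounts, rel=1e-12)

    def test_superposition_of_two_doses(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)

        def solve(rows):
            frame = pd.DataFrame(rows).sort_values("time", kind="stable")
            return solve_schedule_analytic(read_events_table(frame), p)

        obs = [dict(time=t, cmt=2, evid=0) for t in (1.0, 5.0, 30.0)]

        def at_obs(sol):
            view = sol.schedule.observation_view()["1"]
            return sol.amounts[:, view]

        both = at_obs(solve([dict(time=0, amt=800, cmt=1, evid=1),
                             dict(time=12, amt=400, cmt=1, evid=1)] + obs))
        first = at_obs(solve([dict(time=0, amt=800, cmt=1, evid=1)] + obs))
        second = at_obs(solve([dict(time=12, amt=400, cmt=1, evid=1)] + obs))
        combined = first + second
        scale = max(1.0, np.max(np.abs(combined)))
        assert np.max(np.abs(both - combined)) / scale < 1e-10

    def test_steady_state_row_initializes_the_profile(self):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        sched = read_events_table(
            pd.DataFrame(
                [
                    dict(time=0, amt=1200, cmt=1, evid=1, ii=12, ss=1),
                    dict(time=0.0, cmt=2, evid=0),
                ]
            )
        )
        sol = solve_schedule_analytic(sched, p)
        uss = steady_state_state(p, 1200.0, 0.0, 12.0, cmt=1)
        assert sol.amounts[:, 1] == pytest.approx(uss, rel=1e-12)

    def test_per_event_theta_switches_parameters(self):
        slow = TwoCptParams(CL=1.0, Q=15, Vcent=35, Vperi=105, ka=2.0)
        fast = TwoCptParams(CL=50.0, Q=15, Vcent=35, Vperi=105, ka=2.0)
        rows = [
            dict(time=0, amt=1000, cmt=1, evid=1),
            dict(time=6, cmt=2, evid=0),
            dict(time=12, cmt=2, evid=0),
        ]
        sched = read_events_table(pd.DataFrame(rows))
        mixed = solve_schedule_analytic(sched, [slow, slow, fast])
        pure = solve_schedule_analytic(sched, slow)
        # segment ending at the last event uses the fast clearance
        assert mixed.amounts[1, 2] < pure.amounts[1, 2]
        assert mixed.amounts[1, 1] == pytest.approx(pure.amounts[1, 1], rel=1e-12)

    def test_solution_frame_appends_compartment_columns(self, expanded_schedule):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        frame = solve_schedule_analytic(expanded_schedule, p).to_frame()
        assert list(frame.columns[:10]) == [
            "id", "time", "amt", "rate", "ii", "addl", "cmt", "evid", "ss", "dv"
        ]
        assert {"A1", "A2", "A3"} <= set(frame.columns)


class TestFastPath:
    def test_matches_general_solver_on_tutorial_regimen(self, expanded_schedule):
        p = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
        sol = solve_schedule_analytic(expanded_schedule, p)
        dt, da, ot, oi = fastpath.dose_and_obs_times(expanded_schedule)
        u, ok = fastpath.central_amounts_batch(
            "twocpt", dt, da, ot,
            CL=np.array([10.0]), Vcent=np.array([35.0]), ka=np.array([2.0]),
            Q=np.array([15.0]), Vperi=np.array([105.0]),
        )
        assert ok.all()
        ref = sol.amounts[1, oi]
        assert np.max(np.abs(u[0] - ref) / np.maximum(ref.max(), 1.0)) < 1e-12

    def test_one_compartment_bateman(self, expanded_schedule):
        p = OneCptParams(CL=10, Vcent=35, ka=2.0)
        sol = solve_schedule_analytic(expanded_schedule, p, model="onecpt")
        dt, da, ot, oi = fastpath.dose_and_obs_times(expanded_schedule)
        u, ok = fastpath.central_amounts_batch(
            "onecpt", dt, da, ot,
            CL=np.array([10.0]), Vcent=np.array([35.0]), ka=np.array([2.0]),
        )
        assert ok.all()
        ref = sol.amounts[1, oi]
        assert np.max(np.abs(u[0] - ref) / np.maximum(ref.max(), 1.0)) < 1e-12

    def test_degenerate_rates_are_flagged(self):
        u, ok = fastpath.central_amounts_batch(
            "onecpt",
            np.array([0.0]), np.array([100.0]), np.array([1.0]),
            CL=np.array([20.0]), Vcent=np.array([20.0]), ka=np.array([1.0]),
        )
        assert not ok[0]
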