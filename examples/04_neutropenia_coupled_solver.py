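"""Drug-induced neutropenia: the coupled PK/PD solver in action.

The Friberg-Karlsson model is driven by the two-compartment concentration
profile. Because the coupling is one-way, the PK is propagated in closed
form while only the five PD states are integrated numerically; this
script shows the resulting ANC time course and verifies the coupled
solution against integrating the full 8-state system.
"""

import numpy as np

from pmxbayes import (OdeSettings, TwoCptParams, build_tutorial_regimen,
                      solve_schedule_coupled, solve_schedule_numeric)
from pmxbayes.models import FKParams, fk_rhs

pk = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
fk = FKParams(mtt=125.0, circ0=5.0, alpha=3.0e-3, gamma=0.17)
schedule = build_tutorial_regimen(expanded=True)

coupled = solve_schedule_coupled(
    schedule, pk,
    lambda t, ypd, ypk, p: fk_rhs(t, ypd, ypk, fk, pk.Vcent),
    n_pd=5, settings=OdeSettings(rtol=1e-8, atol=1e-8),
)

anc = coupled.amounts[7] + fk.circ0  # circulating pool, absolute scale
times = np.array([r.time for r in schedule.records])
imin = int(np.argmin(anc))
print(f"baseline ANC: {fk.circ0:.2f} x10^3 cells/uL")
print(f"nadir within the observation window: {anc[imin]:.3f} at t = {times[imin]:.0f} h")
print("  (the transit chain delays the nadir well past the dosing phase; "
      f"MTT = {fk.mtt:.0f} h)")


def full_rhs(t, y, packed):
    pkp, fkp = packed
    k10, k12, k21 = pkp.micro_constants()
    dpk = np.array([-pkp.ka * y[0],
                    pkp.ka * y[0] - (k10 + k12) * y[1] + k21 * y[2],
                    k12 * y[1] - k21 * y[2]])
    return np.concatenate([dpk, fk_rhs(t, y[3:], y[:3], fkp, pkp.Vcent)])


full = solve_schedule_numeric(schedule, full_rhs, 8, (pk, fk),
                              settings=OdeSettings(rtol=1e-8, atol=1e-8))
scale = np.maximum(np.max(np.abs(full.amounts[3:]), axis=1, keepdims=True), 1e-12)
err = np.max(np.abs(full.amounts[3:] - coupled.amounts[3:]) / scale)
print(f"coupled (5 numeric states) vs full system (8): max scaled diff {err:.1e}")
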