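"""Genetic switching of the deterministic model.

During the GATA switch, GATA-1 displaces GATA-2 from shared chromatin
sites.  The model represents this as a transient extra GATA-2 degradation
rate k2* on a time window, plus a GATA-1 influx mu * k2* * y.  The
availability parameter mu decides the outcome: full availability commits
the cell to the erythroid lineage, absent GATA-1 (a GATA-2 knockdown)
commits to the myeloid lineage, and intermediate availability fails to
switch -- the cell returns to the primed progenitor state.
"""

from gataswitch import (
    SwitchSchedule,
    figure3_parameters,
    relative_distance,
    simulate_ode,
    steady_state_set,
)

params = figure3_parameters()
states = steady_state_set(params, seed=0)
primed = states.primed.state

scenarios = [
    ("GATA switch (mu=1, k2*=6)", SwitchSchedule(6.0, 500, 1500, 1.0), states.erythroid),
    ("GATA-2 knockdown (mu=0, k2*=20)", SwitchSchedule(20.0, 500, 1500, 0.0), states.myeloid),
    ("intermediate (mu=0.32, k2*=6)", SwitchSchedule(6.0, 500, 1500, 0.32), states.primed),
]

for name, schedule, target in scenarios:
    traj = simulate_ode(params, schedule, primed, t_end=2000.0)
    end = traj.endpoint
    d = relative_distance(end, target.state)
    print(f"{name}:")
    print(f"  endpoint at t=2000 h: x={end[0]:9.3f}  y={end[1]:9.3f}  z={end[2]:9.3f}")
    print(f"  settles at the {target.label} state (relative distance {d:.2e})")

# All three runs start from the primed state; only the window [500, 1500]
# differs.  The endpoint coordinates match the analytic attractors to
# integrator precision, i.e. switching is decided entirely by mu.
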