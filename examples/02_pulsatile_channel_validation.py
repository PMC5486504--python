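"""Validate the flow solver against the analytic pulsatile channel solution.

A straight channel is driven by a single-harmonic inflow at the
physiological Womersley number (~2.3) but a reduced Reynolds number so the
flow develops within the short channel; the simulated centerline velocity
over the last cycle is compared with the exact oscillatory-channel series.
"""

import numpy as np

from hemoshear import (
    FlowConditions,
    Numerics,
    analytic_channel_solution,
    build_channel_mesh,
    simulate_pulsatile,
    womersley_number,
)
from hemoshear import units

cal = 3.2356  # mm, the caliber pinned by the physiological Reynolds number
flow = FlowConditions(mean_flow=20.0, max_flow=32.54, reference_diameter=cal, n_cycles=3)
print(f"Womersley number: {womersley_number(flow):.3f} (physiological ~2.32)")

mesh = build_channel_mesh(8 * cal, cal, cal / 16)
field = simulate_pulsatile(mesh, flow, Numerics(steps_per_cycle=100))

h = units.mm_to_m(cal)
q_mean = flow.mean_velocity() * h
q_amp = q_mean * (flow.max_flow - flow.mean_flow) / flow.mean_flow
i = int(0.75 * mesh.nx)
jm = mesh.ny // 2
u_num = np.array(
    [0.5 * (field.cell_u(k)[i, jm - 1] + field.cell_u(k)[i, jm]) for k in range(len(field.times))]
)
u_ex = analytic_channel_solution(
    h, q_mean, q_amp, flow.heart_rate / 60.0, flow.density, flow.viscosity,
    field.times + 2 * flow.period, h / 2,
)
rel = np.linalg.norm(u_num - u_ex) / np.linalg.norm(u_ex)
print(f"centerline velocity, last cycle: relative L2 error vs analytic = {rel:.3%}")
# ~1% at this resolution: the solver reproduces the phase lag and flattened
# profile of pulsatile channel flow, not just the mean.
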