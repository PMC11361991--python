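"""Bang-bang valve control: full-scale step and waveform tracking.

Simulates the supply/exhaust dead-band controller on a first-order
pneumatic chamber: the worst-case 0 -> 50 kPa step, then tracking of the
three clinical pressurization waveforms at 30 kPa.
"""

import numpy as np

from respiromech import (
    BreathPattern,
    ControllerConfig,
    PlantParams,
    RobotPressureProgram,
    simulate_pneumatics,
    step_metrics,
    tracking_mae,
)
from respiromech.waveforms import actuator_reference

plant = PlantParams()
cfg = ControllerConfig(target=50.0, threshold=5.0)
t, trace = simulate_pneumatics(plant, cfg, 5.0)
m = step_metrics(trace, 50.0, cfg.dt)
print(f"50 kPa step: rise {m['rise_time_s']:.2f} s, settle {m['settling_time_s']:.2f} s,"
      f" overshoot {m['overshoot_kPa']:.2f} kPa")

pattern = BreathPattern(T=6.0, f_insp=0.5, A_rc=0.0, A_dim=0.0)
dt = 0.01
t_grid = np.arange(int(round(18.0 / dt)) + 1) * dt
for shape in ("square", "triangle", "sine"):
    ref = actuator_reference(RobotPressureProgram(shape, 30.0), pattern, t_grid)
    _, trace = simulate_pneumatics(plant, ControllerConfig(target=ref, threshold=3.0), 18.0)
    print(f"{shape:8s} tracking MAE {tracking_mae(trace, ref):.2f} kPa")
print("(the dead band trades steady-state accuracy for chatter-free valves)")
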