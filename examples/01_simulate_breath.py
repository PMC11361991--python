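"""Simulate one spontaneous breath and read off excursion and tidal volume.

Builds half-sine muscle drives for a 6 s breath, integrates the coupled
two-compartment model, and prints the diaphragm excursion (peak-to-trough
displacement, cm) and the lung volume swing (L) of the last breath.
"""

import numpy as np

from respiromech import BreathPattern, MechanicalParameters, build_drives, simulate

pattern = BreathPattern(T=6.0, f_insp=0.5, A_rc=1.07, A_dim=2.46)
t = np.arange(0, 3 * pattern.T, 0.02)
traj = simulate(MechanicalParameters(), build_drives(pattern, t))

last = t >= 2 * pattern.T
excursion = np.ptp(traj.x_di[last])
vt = np.ptp(traj.V_l[last])
print(f"diaphragm excursion : {excursion:.3f} cm")
print(f"lung volume swing   : {vt:.3f} L")
print("(the excursion is what M-mode ultrasound would measure per breath;")
print(" the volume swing is the tidal volume a spirometer would integrate)")
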