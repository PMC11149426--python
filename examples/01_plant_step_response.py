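"""Step response of the tendon-driven eye plant.

Builds the default human-like right-eye plant, solves the static commands
that hold straight-ahead fixation, then winds the lateral rectus cable by
2.5 mm and integrates for 400 ms.  Prints the final azimuth, the peak eye
speed and the overshoot -- which is zero, because the plant is overdamped.
"""

import numpy as np

from bioeye import EyeState, default_plant
from bioeye.rotation import angles_from_rotvec

plant = default_plant()
u_hold = plant.solve_fixation_tensions(np.zeros(3))
print("holding commands (mm):",
      dict(zip("LR MR SR IR SO IO".split(), np.round(u_hold, 3))))

u = np.repeat(u_hold[:, None], 400, axis=1)
u[plant.muscle_index("LR")] += 2.5
traj = plant.simulate(u, EyeState())

azimuth = np.array([angles_from_rotvec(r)[0] for r in traj.r])
speed = np.degrees(np.linalg.norm(traj.w, axis=1))
print(f"final azimuth : {azimuth[-1]:6.2f} deg (rightward, LR abducts)")
print(f"peak speed    : {speed.max():6.1f} deg/s")
print(f"overshoot     : {azimuth.max() - azimuth[-1]:6.3f} deg "
      "(0 = monotone approach)")
print(f"min tension   : {traj.tensions.min():6.3f} N (never negative: "
      "tendons pull, they cannot push)")
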