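"""A small saccade campaign and its 3D kinematic analysis.

Runs a 12-saccade continuous paradigm (each saccade starts where the last
one ended), then computes the standard oculomotor summaries: endpoint
accuracy regressions, the main-sequence fits and the saturation velocity
they imply, trajectory curvature, and the Listing-plane fit through the
fixation orientations.  Takes a minute or so.
"""

import numpy as np

from bioeye import ParadigmConfig, default_plant
from bioeye import analysis as an
from bioeye.experiments import run_continuous

plant = default_plant()
ds = run_continuous(ParadigmConfig("continuous", n=12, seed=7), plant=plant)

targets = np.array([[np.degrees(-2 * np.arctan(r.goal.gz)),
                     np.degrees(-2 * np.arctan(r.goal.gy))]
                    for r in ds.records])
endpoints = np.array([m.offset for m in ds.metrics])
acc = an.accuracy_regression(targets, endpoints)
print(f"accuracy: theta_H = {acc.a:+.2f} + {acc.b:.3f} T_H (r2={acc.r2_h:.4f});"
      f" phi_V = {acc.c:+.2f} + {acc.d:.3f} T_V (r2={acc.r2_v:.4f})")

amps = [m.amplitude for m in ds.metrics]
ms = an.main_sequence_fit(amps, [m.duration_ms for m in ds.metrics],
                          [m.v_peak for m in ds.metrics])
print(f"main sequence: D = {ms.e:.0f} + {ms.f:.1f} R (ms);  "
      f"V_PK*D = {ms.k:.2f} + {ms.m:.2f} R (deg)")
print(f"  -> predicted saturation velocity {ms.saturation_velocity:.0f} deg/s")

cs = [an.curvature(an.gaze_angles(t.r)).c for t in ds.trajectories]
print(f"curvature: median |C| = {np.median(np.abs(cs)):.3f} "
      f"({np.mean(np.abs(np.array(cs)) < 0.15):.0%} of saccades below the "
      "'really curved' threshold 0.15)")

lp = an.fit_listing_plane(np.array([r.trajectory.r[-1] for r in ds.records]))
print(f"Listing plane (fixations): r_x = {lp.alpha:+.3f} r_y {lp.beta:+.3f} r_z;"
      f" width = {lp.sigma_deg:.2f} deg, tilt = {lp.tilt_deg:+.2f} deg")
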