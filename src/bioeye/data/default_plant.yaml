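# Default plant configuration: a right eye with six pull-only elastic tendons.
#
# Coordinates are in mm in the head-fixed lab frame: x frontal (out of the
# pupil at straight-ahead), y leftward, z upward.  Insertions are on the globe
# surface (eye frame; the loader projects them exactly onto the sphere).
# Anchors are fixed head-frame points: the common recti origin emulates the
# annulus of Zinn, displaced nasally (leftward, +y) behind the right eye; the
# SO and IO are routed through orbital pulley points (trochlea-like), so their
# pulling direction is insertion -> pulley.
#
# Insertion/origin placement is digitized from standard human-eye anatomy and
# scaled to a 12 mm globe.  Stiffness, damping and pretension are calibrated
# so that the default plant is overdamped and optimal saccades land on a
# human-like main sequence (peak velocities of a few hundred deg/s).
globe_radius_mm: 12.0
muscles:
  LR: {insertion: [6.88, -9.83, 0.0],   anchor: [-34.0, 4.0, 0.6],  pulley: false, gain: 1.0}
  MR: {insertion: [9.19, 7.71, 0.0],    anchor: [-34.0, 4.0, 0.6],  pulley: false, gain: 1.0}
  SR: {insertion: [6.88, 0.0, 9.83],    anchor: [-34.0, 4.0, 0.6],  pulley: false, gain: 1.0}
  IR: {insertion: [7.28, 0.0, -9.54],   anchor: [-34.0, 4.0, 0.6],  pulley: false, gain: 1.0}
  SO: {insertion: [-5.06, -5.06, 9.64], anchor: [6.0, 13.0, 12.0],  pulley: true,  gain: 1.0}
  IO: {insertion: [-3.60, -7.21, -8.89], anchor: [9.0, 13.0, -11.0], pulley: true,  gain: 1.0}
params:
  inertia_kg_mm2: [0.45, 0.44, 0.42]   # eye-frame diagonal (camera payload -> mildly anisotropic)
  damping_nmm_s_per_rad: 14.0
  stiffness_n_per_mm: 1.0
  pretension_n: 2.0
  tension_floor_n: 0.05
  dt_s: 0.001
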