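# Methods

## The plant

The eye is a rigid sphere of radius 12 mm rotating about its fixed centre.
Orientation is kept as an Euler–Rodrigues rotation vector
**r** = tan(θ/2)·**n** (half-radian components) in a head-fixed right-handed
frame: x frontal (cyclo-torsion, clockwise positive), y horizontal axis
(vertical rotation, downward positive), z vertical axis (horizontal
rotation, leftward positive).  The exact maps between the orientation rate
ṙ and the angular velocity ω (and back) carry the non-commutativity of 3D
rotations; they are implemented without small-angle approximations and
verified in tests against an independent unit-quaternion oracle.
Orientations approaching a rotation angle of π, where the tan-half-angle
chart degenerates, raise an error instead of being regularized — the
oculomotor workspace stays below ~35°.

Six tendons (LR, MR, SR, IR, SO, IO) run as straight segments from
insertions on the globe to fixed head-frame anchors.  The four recti share
a common origin displaced nasally behind the eye (emulating the annulus of
Zinn of a right eye); the obliques are routed through anterior orbital
pulley points, so their pulling directions are insertion → pulley.  As the
eye rotates, insertions move with it: pulling directions, moment arms and
path lengths are all orientation-dependent.  Tendon force is a linear
spring around a pretension level defined at straight-ahead fixation,

    T_i = max(0, T_pre + k·(ΔL_i(r) + u_i)),

where ΔL_i is the geometric path-length change and u_i the commanded cable
shortening (mm, the motor spindle winding).  The zero clamp encodes that
muscles cannot push; the pretension (set by calibration, see below) keeps
tendons taut during ordinary movements.  Torque is Σ p_i × T_i·d̂_i minus a
viscous term B·ω standing in for the bearing friction of a physical mount;
Coulomb friction is not modelled.  The moment of inertia is a mildly
anisotropic eye-frame tensor (a camera payload breaks isotropy), rotated
with the eye, so I(r) is orientation-dependent; a single isotropic value
can be configured instead.

### Parameters (defaults, `src/bioeye/data/default_plant.yaml`)

| parameter | value | units | why |
|---|---|---|---|
| globe radius | 12 | mm | human-scale eye |
| inertia diag | 0.45/0.44/0.42 | kg·mm² | sphere + camera payload |
| damping B | 14 | N·mm·s/rad | overdamped: no overshoot anywhere in the workspace |
| stiffness k | 1.0 | N/mm | with the geometry, rotational stiffness ~10² N·mm/rad |
| pretension T_pre | 2.0 | N | antagonists stay taut during ordinary saccades |
| tension floor | 0.05 | N | static solver margin above slack |
| step | 1 ms | | command sample rate |

Insertion/anchor coordinates are digitized from standard human-eye anatomy
and scaled to the globe; the exact placement (notably the vertical-recti
moment arms) was calibrated, together with k, B and T_pre, so that the
*optimally controlled* plant lands on a human-like main sequence (peak
velocities of a few hundred deg/s, durations growing roughly affinely with
amplitude) and shows the direction anisotropy of real saccades (vertical
faster than horizontal at matched amplitude).  These defaults are the
package's own calibration, not measured constants; everything is editable
through the YAML config.

### Integration

The plant is viscosity-dominated: the velocity relaxation time I/B is
~0.03 ms, far below the 1 ms command step, so explicit integration of the
velocity equation is unstable at any useful step.  The integrator treats
the damping torque implicitly,

    (I(r) + 1000·h·B·Id) ω⁺ = I(r) ω + h (1000·τ_muscle − 10⁻³ ω×I(r)ω),

(the factors convert the mixed N·mm / kg·mm² units to SI and back), then
advances r with ω⁺ — unconditionally stable in the stiff direction and
accurate for the slow orientation dynamics (within 0.04% of a
fine-substepped RK4 reference over 100 ms at the default single substep;
the reference integrator ships in `Plant.simulate_rk4`).  Simulation is
deterministic: identical inputs give bit-identical trajectories.

### Statics

Holding an orientation is three linear constraints (zero torque) on six
commands; `solve_fixation_tensions` returns the minimum-norm command vector
with all tensions at or above the slack floor, via least squares plus an
active-set fallback that pins floor-violating tendons.  The static
workspace — orientations where such a solution exists — extends beyond
|r| = 0.35 in every direction, so the goal disc |(G_y, G_z)| ≤ 0.3
(eccentricities to ~33°) is feasible with margin; the corners of the
±0.3-per-component box are not, which is why paradigms sample the disc.
A by-product of the nasally displaced recti origin: the LR static tension
at straight-ahead slightly exceeds the MR's (the LR path is longer), and
the fixation Listing plane is slightly tilted.

## The controller

For a goal x_G = (0, G_y, G_z, 0, 0, 0) and a candidate duration D from
{30, 50, …, 210} ms, the six command time courses are parameterized as
knots every 10 ms with linear interpolation (bounds −8…+14 mm) and
optimized by L-BFGS-B; gradients are forward differences evaluated inside
the compiled simulator core.  The cost is

    J_MOV(D) = λ_A (‖r(D)−r_G‖² + w_ω‖ω(D)‖²) + λ_D D/(1+γD) + λ_E Σ∫(du/dt)²dt

with defaults λ_A = 10⁴, λ_D = 10⁻², λ_E = 10⁻⁴, w_ω = 10⁻⁴, γ = 5·10⁻³/ms,
chosen so that one degree of endpoint error, twenty milliseconds of extra
duration and a typical saccade's motor energy all cost the same order of
magnitude — which makes J_MOV(D) convex with an interior minimum over the
5–30° amplitude range (`bioeye calibrate` prints the profile).  The small
w_ω term implements the goal's zero endpoint velocity; endpoint torsion is
penalized through r_G,x = 0 — no explicit Listing constraint exists
anywhere in the model.

Each duration is solved from a fresh initialization (a ramp between the
static holding commands of the start and goal fixations, plus seeded
jitter).  Warm-starting successive durations from each other was tried and
rejected: it occasionally propagates a trapped local optimum — a
higher-energy solution in which the antagonist co-moves instead of showing
its anti-pulse — down the whole grid.  The outer loop takes the duration
with minimal total cost (ties toward shorter D); an optional early stop
abandons the scan after the convex profile has risen a configurable number
of times past the bracketed minimum (paradigm campaigns use 2; the default
is the full grid).  Energy is integrated strictly inside [0, D], so the
command may step discontinuously at movement onset; this front-loads the
pulse, as in recorded motoneuron bursts.

What emerges, without being asked for: pulse-step agonists and
anti-pulse/anti-step antagonists, negative within-saccade LR–MR
correlations for horizontal saccades, approximately straight oblique
trajectories, durations that grow with amplitude, saturating peak
velocities, and fixation orientations confined to a plane.

## Paradigms and stimulation

Three campaigns generate datasets: `zero_initial` (all saccades from
straight ahead; desk scale 30, published scale 199), `continuous` (each
saccade starts where the previous ended; 50/298), and
`horizontal_continuous` (chained, goals on a 0.012 rad/2 grid along the
horizontal meridian; 30/202).  Goals are drawn uniformly over the disc
|(G_y, G_z)| ≤ 0.3 rad/2 — amplitudes reach ~33° from centre and ~50+°
across the workspace in the chained paradigm — with a single seed fanned
out to per-stage seeds, so every dataset is exactly reproducible.

Stimulation experiments hold the eye at an eccentric fixation, superpose a
Gaussian pulse (default width 21 ms FWHM; amplitude defaulting to the peak
agonist drive of a 10° optimal saccade) on one muscle's holding command and
integrate the response.  The torsion measure Δr_x integrates ṙ_x from pulse
start to movement offset, taken as the eye speed falling below 1 deg/s or
its first local minimum after the pulse-driven peak — the elastically
restoring plant then begins drifting back to the held fixation, and
integrating through that passive return would cancel the displacement being
measured.  LR/MR stimulation from vertical eccentricities yields torsion
linear in the initial elevation (r² > 0.95) with opposite slopes; SO
stimulation from horizontal eccentricities yields a dominant intorsion
whose position dependence carries a clear linear trend over a shallow
symmetric component (linear r² ≈ 0.7 over ±0.24 rad/2 — a property of this
plant's oblique geometry, asserted as such in the tests).

## The surrogate

An optional identification stage replaces the simulator inside the
optimizer.  Excitation is a PRBS: per muscle, two command levels (default
±1 mm around the straight-ahead holding command) switched at exponentially
distributed hold times (mean 30 ms), 2·10⁵ ms at desk scale.  The surrogate
is a NARX-style map: the state increment is ridge-regressed on delay taps
of commands and states (2 + 2) plus quadratic features (state⊗state and
command⊗state, the latter capturing orientation-dependent muscle action);
it runs closed loop on its own feedback.  Held-out closed-loop NRMSE is
~2% per state channel, and commands optimized against the surrogate and
replayed on the plant land within a degree of the plant-optimized endpoint
for small test saccades.

Stated limitation: the surrogate is trustworthy inside its identification
envelope.  Wide-excitation PRBS drives the unconstrained plant far outside
the mechanical workspace (|r| > 1 rad/2, where the straight-path muscle
model is meaningless), and no stable fit of that regime was found in this
model class (episodic resets, guarded excitation and noise-injected
training were all evaluated).  Large saccades therefore use the default
plant-direct optimization path; the surrogate remains the fast path for
small movements and a demonstration of the identification pipeline.

## Analysis conventions

Gaze angles: azimuth θ_H = −2·arctan(r_z), elevation ϕ_V = −2·arctan(r_y),
in degrees, rightward/upward positive.  Vectorial peak velocity is the
maximum of ‖ω‖ in deg/s (switchable to the coordinate velocity); component
peak velocities use gaze-angle derivatives.  Saccades produced by the
optimizer span exactly [0, D], so onset/offset are the first/last samples.
Curvature translates the planar trace to the origin, rotates the chord onto
+x, and reports the extreme signed perpendicular deviation over the chord
length (clockwise positive; a rightward semicircle with an upper arc gives
−0.5); it is invariant to rotation/translation of the trace and flips sign
under reflection.  The Listing-plane fit is ordinary least squares of r_x
on (r_y, r_z) through the origin; the residual width σ is reported both in
rad/2 and as 2·arctan(σ) in degrees, and the tilt as −arctan(α).  The
position-gain regression z-scores peak speed, |ΔH| and the contralateral
initial eccentricity (−sign(ΔH)·H_on) for movements ≥ 6°, and assesses the
added position regressor with a nested-model F test.  Direction bins are
30° wide; curvature-versus-direction summaries use 20° windows with 10°
overlap.

## What the synthetic campaigns do and do not show

All data are generated by the model itself; there is no sensor noise, no
motor noise, and no trial-to-trial variability beyond the seeded goal
sequence.  Passing tests therefore show that the *mechanics-plus-optimal-
control* account reproduces the structure of real saccades (main sequence,
Listing plane, synergies, cross-coupling), not that the parameter values
match any particular eye.  Velocity profiles are more symmetric than human
ones (which are negatively skewed); multiplicative signal-dependent motor
noise, which skews them, is out of scope.  Transient torsion during large
chained saccades thickens the pooled orientation cloud to σ ≈ 1.5° even
though fixation orientations stay planar well below 1° — a stronger
movement-related thickening than in the published robotic data.  Soft-tissue
recti pulleys, globe wrapping of muscle paths, side-slip constraints and
Hill-type muscle nonlinearity are deliberately absent, as are the hardware
prototype's motor dynamics.
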