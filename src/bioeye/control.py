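"""Optimal saccade control: speed-accuracy-energy trade-off.

A saccade to a goal orientation is found in two nested loops.  The inner
loop, for a candidate movement duration ``D`` on a coarse grid (30-210 ms in
20 ms steps), optimizes the six motor-command time courses to minimize

    J_MOV(D) = lambda_A * J_A(D) + lambda_D * J_D(D) + lambda_E * J_E(D)

where J_A is the squared endpoint error (orientation, plus a small weight on
residual angular velocity so the movement actually stops at the goal state),
J_D = D / (1 + gamma D) is a hyperbolic reward-discount duration cost, and
J_E = integral (du/dt)^2 dt is the kinetic energy spent by the six motors.
The outer loop picks the duration with the lowest total cost (ties broken
toward shorter D).  The weights produce a convex J_MOV(D) with an interior
minimum over the 5-30 deg amplitude range.

Commands are parameterized as per-muscle knots every 10 ms with linear
interpolation, optimized by L-BFGS-B with forward-difference gradients
evaluated in the compiled plant core; pulse-step agonist/antagonist command
shapes are not imposed -- they emerge from the optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _engine
from .plant import EyeState, Plant, Trajectory

__all__ = [
    "Goal",
    "CostWeights",
    "ControlParameterization",
    "OptimalSaccade",
    "DEFAULT_WEIGHTS",
    "DURATION_GRID_MS",
    "accuracy_cost",
    "duration_cost",
    "energy_cost",
    "total_cost",
    "optimize_for_duration",
    "optimal_saccade",
]

DURATION_GRID_MS = tuple(range(30, 211, 20))

_GOAL_RANGE = 0.3  # rad/2, the oculomotor workspace bound per component


@dataclass(frozen=True)
class Goal:
    """A stationary saccade target: orientation (0, gy, gz) in rad/2 with a
    zero torsional component (this, not an explicit constraint, is what
    induces Listing-like behaviour) and zero target angular velocity."""

    gy: float
    gz: float

    def __post_init__(self):
        if not (np.isfinite(self.gy) and np.isfinite(self.gz)):
            raise ValueError("goal components must be finite")
        if max(abs(self.gy), abs(self.gz)) > _GOAL_RANGE + 1e-9:
            raise ValueError(
                f"goal outside the +/-{_GOAL_RANGE} rad/2 oculomotor range")

    @property
    def r(self) -> np.ndarray:
        return np.array([0.0, self.gy, self.gz])


@dataclass(frozen=True)
class CostWeights:
    """Weights of the three sub-costs plus shape constants.

    ``lam_a`` multiplies squared rad/2 endpoint error, ``lam_d`` the
    hyperbolic duration cost (D in ms), ``lam_e`` the motor kinetic energy
    ((mm/s)^2 * s).  ``w_omega`` weighs the residual endpoint angular
    velocity (rad/s)^2 inside J_A; ``gamma`` (1/ms) sets the curvature of
    the hyperbolic duration discount."""

    lam_a: float = 1.0e4
    lam_d: float = 1.0e-2
    lam_e: float = 1.0e-4
    w_omega: float = 1.0e-4
    gamma: float = 5.0e-3

    def __post_init__(self):
        if min(self.lam_a, self.lam_d, self.lam_e, self.w_omega) < 0:
            raise ValueError("cost weights must be non-negative")


DEFAULT_WEIGHTS = CostWeights()


@dataclass(frozen=True)
class ControlParameterization:
    knot_ms: int = 10          # knot spacing in samples (= ms)
    u_min: float = -8.0        # mm, largest commanded lengthening
    u_max: float = 14.0        # mm, largest commanded shortening


# ------------------------------------------------------------------- costs


def accuracy_cost(traj: Trajectory, goal: Goal, w_omega: float = 0.0) -> float:
    """Squared endpoint error ||r(D) - r_G||^2 + w_omega ||omega(D)||^2."""
    err = traj.r[-1] - goal.r
    return float(err @ err + w_omega * (traj.w[-1] @ traj.w[-1]))


def duration_cost(d_ms: float, gamma: float = DEFAULT_WEIGHTS.gamma) -> float:
    """Hyperbolic duration cost D/(1 + gamma D): zero at D=0, strictly
    increasing and concave (discounted reward)."""
    if d_ms < 0:
        raise ValueError("duration must be non-negative")
    return float(d_ms / (1.0 + gamma * d_ms))


def energy_cost(controls, dt: float = 1e-3) -> float:
    """Total motor kinetic energy: sum_i integral (du_i/dt)^2 dt, evaluated
    on the 1 ms command signal ((mm/s)^2 * s)."""
    u = np.asarray(controls, dtype=float)
    du = np.diff(u, axis=1) / dt
    return float(np.sum(du * du) * dt)


def total_cost(traj: Trajectory, controls, goal: Goal, d_ms: float,
               weights: CostWeights = DEFAULT_WEIGHTS) -> float:
    """J_MOV = lam_A J_A + lam_D J_D + lam_E J_E (exact weighted sum)."""
    return (weights.lam_a * accuracy_cost(traj, goal, weights.w_omega)
            + weights.lam_d * duration_cost(d_ms, weights.gamma)
            + weights.lam_e * energy_cost(controls))


# --------------------------------------------------------------- optimizer


@dataclass
class OptimizedControl:
    """Inner-loop result for one candidate duration."""

    d_ms: int
    controls: np.ndarray          # (6, D+1) at 1 ms
    knots: np.ndarray             # (6, nk)
    j_mov: float
    j_a: float
    j_d: float
    j_e: float
    endpoint_error_deg: float
    converged: bool
    n_iter: int


@dataclass
class OptimalSaccade:
    """Outer-loop result: the duration of minimal total cost and its
    optimized command, plus the realized plant trajectory."""

    goal: Goal
    start: EyeState
    d_ms: int
    controls: np.ndarray
    trajectory: Trajectory
    j_mov: float
    j_a: float
    j_d: float
    j_e: float
    per_duration: dict = field(default_factory=dict)   # D -> J_MOV(D)

    @property
    def duration_costs(self) -> np.ndarray:
        return np.array([self.per_duration[d] for d in sorted(self.per_duration)])


def _hold_knots(plant: Plant, r_a, r_b, nk: int) -> np.ndarray:
    """Initial guess: ramp from the commands holding r_a to those holding
    r_b over the first ~60% of knots, then hold."""
    ua = plant.solve_fixation_tensions(r_a)
    ub = plant.solve_fixation_tensions(r_b)
    ramp_end = max(1, int(0.6 * (nk - 1)))
    knots = np.empty((6, nk))
    for j in range(nk):
        a = min(1.0, j / ramp_end)
        knots[:, j] = (1 - a) * ua + a * ub
    return knots


def optimize_for_duration(goal: Goal, x0: EyeState, d_ms: int,
                          weights: CostWeights = DEFAULT_WEIGHTS,
                          model: Plant | object = None,
                          param: ControlParameterization = ControlParameterization(),
                          init_knots: np.ndarray | None = None,
                          maxiter: int = 60,
                          seed: int | None = None) -> OptimizedControl:
    """Locally optimal knotted command for a fixed duration.

    ``model`` is the system the optimizer differentiates through: a
    :class:`~bioeye.plant.Plant` (default, compiled fast path) or any object
    with an ``endpoint(controls, x0)`` method returning (r_D, w_D) -- in
    particular a trained surrogate.  A non-converged optimizer run is
    returned flagged, so the outer loop can exclude it.
    """
    if model is None:
        raise ValueError("a plant or surrogate model is required")
    if d_ms % param.knot_ms:
        raise ValueError("duration must be a multiple of the knot spacing")
    T = d_ms + 1
    nk = d_ms // param.knot_ms + 1
    if init_knots is None:
        if isinstance(model, Plant):
            init_knots = _hold_knots(model, x0.r, goal.r, nk)
        else:
            init_knots = np.zeros((6, nk))
        if seed is not None:
            rng = np.random.default_rng(seed)
            init_knots = init_knots + rng.normal(0.0, 0.02, init_knots.shape)
    theta0 = np.ascontiguousarray(init_knots, dtype=float).reshape(-1)
    bounds = [(param.u_min, param.u_max)] * theta0.size
    jd = duration_cost(d_ms, weights.gamma)

    if isinstance(model, Plant):
        args = (float(param.knot_ms), T, x0.r.copy(), x0.w.copy(), goal.r,
                *model._engine_args(), model._inertia,
                model.params.dt, model.params.substeps,
                weights.lam_a, weights.lam_e, weights.w_omega, 1e-6)

        def fun(theta):
            j, g = _engine.cost_and_grad(np.ascontiguousarray(theta), *args)
            return j + weights.lam_d * jd, g

        res = minimize(fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    else:
        dt = 1e-3

        def fun(theta):
            u = _engine._interp_knots(theta.reshape(6, nk), float(param.knot_ms), T)
            r_end, w_end = model.endpoint(u, x0)
            err = r_end - goal.r
            ja = err @ err + weights.w_omega * (w_end @ w_end)
            du = np.diff(u, axis=1) / dt
            je = float(np.sum(du * du) * dt)
            return weights.lam_a * ja + weights.lam_e * je + weights.lam_d * jd

        res = minimize(fun, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12})

    knots = res.x.reshape(6, nk)
    u = np.asarray(_engine._interp_knots(knots, float(param.knot_ms), T))
    if isinstance(model, Plant):
        traj = model.simulate(u, x0)
        r_end, w_end = traj.r[-1], traj.w[-1]
    else:
        r_end, w_end = model.endpoint(u, x0)
    err = r_end - goal.r
    ja = float(err @ err + weights.w_omega * (w_end @ w_end))
    je = energy_cost(u)
    jmov = weights.lam_a * ja + weights.lam_d * jd + weights.lam_e * je
    # endpoint error as a gaze angle (deg): 2*arctan of the residual chord
    err_deg = float(np.degrees(2.0 * np.arctan(np.linalg.norm(err))))
    converged = bool(res.success or res.status == 1)  # 1 = maxiter reached
    return OptimizedControl(d_ms, u, knots, jmov, ja, jd, je, err_deg,
                            converged, int(res.nit))


def optimal_saccade(goal: Goal, x0: EyeState,
                    weights: CostWeights = DEFAULT_WEIGHTS,
                    model: Plant | object = None,
                    plant: Plant | None = None,
                    param: ControlParameterization = ControlParameterization(),
                    durations=DURATION_GRID_MS,
                    maxiter: int = 60,
                    seed: int | None = None,
                    early_stop: int = 0) -> OptimalSaccade:
    """Full two-loop optimal saccade: optimize each duration on the grid,
    pick the arg-min of J_MOV (ties toward shorter D), and realize the
    winning command on the physics plant.

    When ``model`` is a surrogate, ``plant`` supplies the physics simulator
    used for the final replay (the optimize-on-approximator, replay-on-plant
    hand-off); when ``model`` is the plant itself, replay is on that plant.

    ``early_stop`` > 0 walks the (convex) duration profile in increasing
    order and abandons the scan after that many consecutive cost increases
    beyond the bracketed minimum; 0 evaluates the full grid.
    """
    if model is None:
        raise ValueError("a plant or surrogate model is required")
    if plant is None:
        if not isinstance(model, Plant):
            raise ValueError("replay plant required when optimizing a surrogate")
        plant = model
    best: OptimizedControl | None = None
    per_duration: dict[int, float] = {}
    rising = 0
    # each duration is solved from the fresh ramp initialization: chaining
    # warm starts across durations occasionally hands a trapped local
    # optimum down the grid, whereas independent solves stay robust
    for d in durations:
        res = optimize_for_duration(goal, x0, d, weights, model, param,
                                    maxiter=maxiter, seed=seed)
        if not res.converged:
            continue
        per_duration[d] = res.j_mov
        if best is None or res.j_mov < best.j_mov - 1e-12:
            best = res
            rising = 0
        else:
            rising += 1
            if early_stop and rising >= early_stop:
                break
    if best is None:
        raise RuntimeError("optimizer failed to converge for every duration")
    traj = plant.simulate(best.controls, x0)
    return OptimalSaccade(goal, x0.copy(), best.d_ms, best.controls, traj,
                          best.j_mov, best.j_a, best.j_d, best.j_e,
                          per_duration)
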