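"""Tendon-driven rigid-body model of the biomimetic eye.

The globe is a sphere rotating about its fixed center under the net torque of
six pull-only elastic tendons (LR, MR, SR, IR and the pulley-routed SO, IO)
plus a viscous damping term standing in for the bearing friction of the
physical mount.  Each tendon runs as a straight line from its (eye-fixed,
rotating) insertion point to a fixed head-frame anchor -- the common recti
origin or an orbital pulley -- so pulling directions, moment arms and path
lengths all change with 3D eye orientation.  Tendons are linear springs with
a common stiffness ``k`` and a pretension ``T_pre`` defined at the
straight-ahead fixation; commanded cable shortening ``u_i`` (mm, the motor
spindle winding) adds to the geometric stretch, and tension clamps at zero
(slack) because muscles cannot push.

Newton-Euler dynamics with an orientation-dependent moment of inertia
(the eye-frame tensor is mildly anisotropic) are integrated with a
semi-implicit Euler scheme at 1 ms; an RK4 reference integrator is provided
for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from . import _engine

MUSCLES = ("LR", "MR", "SR", "IR", "SO", "IO")

__all__ = [
    "MUSCLES",
    "MuscleGeometry",
    "PlantParameters",
    "EyeState",
    "Trajectory",
    "Plant",
    "load_plant",
    "default_plant",
]


@dataclass(frozen=True)
class MuscleGeometry:
    """One tendon: insertion on the globe (eye frame, mm), fixed anchor
    (head frame, mm; the muscle origin, or a pulley point for SO/IO), and
    the motor gain (mm of cable shortening per command unit)."""

    name: str
    insertion: np.ndarray
    anchor: np.ndarray
    is_pulley: bool = False
    gain: float = 1.0


@dataclass(frozen=True)
class PlantParameters:
    globe_radius: float = 12.0            # mm
    inertia: tuple = (0.45, 0.44, 0.42)   # kg*mm^2, eye-frame diagonal
    damping: float = 14.0                 # N*mm*s/rad
    stiffness: float = 1.0                # N/mm
    pretension: float = 2.0               # N at the (0,0,0) fixation
    tension_floor: float = 0.05           # N, lowest admissible static tension
    dt: float = 1e-3                      # s, command sample step
    substeps: int = 1                     # integration substeps per sample

    def __post_init__(self):
        for name in ("globe_radius", "damping", "stiffness", "pretension", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(i <= 0 for i in self.inertia):
            raise ValueError("inertia diagonal must be positive")


@dataclass
class EyeState:
    """State of the globe: orientation (rotation vector, rad/2) and angular
    velocity (rad/s, head frame)."""

    r: np.ndarray = field(default_factory=lambda: np.zeros(3))
    w: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float).reshape(3)
        self.w = np.asarray(self.w, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.w))):
            raise ValueError("non-finite eye state")

    def copy(self) -> "EyeState":
        return EyeState(self.r.copy(), self.w.copy())


@dataclass
class Trajectory:
    """A simulated movement sampled at the integration step (1 ms).

    Arrays are time-major: ``r``/``w``/``rdot`` are (T,3); ``tensions`` and
    ``u`` are (T,6) / (6,T) respectively.  Tensions are guaranteed
    non-negative (slack clamp)."""

    t_ms: np.ndarray
    r: np.ndarray
    w: np.ndarray
    rdot: np.ndarray
    tensions: np.ndarray
    u: np.ndarray

    def __len__(self) -> int:
        return self.r.shape[0]

    @property
    def final_state(self) -> EyeState:
        return EyeState(self.r[-1].copy(), self.w[-1].copy())


class Plant:
    """The assembled eye plant: geometry + parameters + integrator."""

    def __init__(self, muscles: list[MuscleGeometry], params: PlantParameters):
        if len(muscles) != 6 or {m.name for m in muscles} != set(MUSCLES):
            raise ValueError(f"exactly the six muscles {MUSCLES} are required")
        order = {n: i for i, n in enumerate(MUSCLES)}
        muscles = sorted(muscles, key=lambda m: order[m.name])
        self.muscles = muscles
        self.params = params
        ins = np.stack([m.insertion for m in muscles], axis=1).astype(float)
        # insertions must lie on the globe surface; project exactly
        norms = np.linalg.norm(ins, axis=0)
        if np.any(np.abs(norms - params.globe_radius) > 0.05 * params.globe_radius):
            raise ValueError("insertion points must lie on the globe surface")
        self._ins = ins * (params.globe_radius / norms)
        self._anch = np.stack([m.anchor for m in muscles], axis=1).astype(float)
        self._gains = np.array([m.gain for m in muscles], dtype=float)
        self._inertia = np.asarray(params.inertia, dtype=float)
        # rest path lengths at straight-ahead, so tension(r=0, u=0) = T_pre
        self._L0 = np.linalg.norm(self._anch - self._ins, axis=0)
        if np.any(self._L0 <= 0):
            raise ValueError("zero-length muscle path at reference orientation")

    # -------------------------------------------------------------- geometry

    def muscle_index(self, name: str) -> int:
        return MUSCLES.index(name)

    def muscle_direction(self, name: str, r) -> tuple[np.ndarray, float]:
        """Unit pulling direction (head frame) and current path length (mm)
        of one tendon at orientation ``r``: the straight segment from the
        rotated insertion to the anchor (origin, or pulley for SO/IO)."""
        i = self.muscle_index(name)
        from .rotation import rotation_matrix
        p = rotation_matrix(r) @ self._ins[:, i]
        d = self._anch[:, i] - p
        L = float(np.linalg.norm(d))
        if L <= 1e-9:
            raise ValueError(f"zero-length path for muscle {name}")
        return d / L, L

    def tendon_tension(self, name: str, r, u_i: float) -> float:
        """Tension (N) of one tendon: max(0, T_pre + k*(stretch + gain*u))."""
        i = self.muscle_index(name)
        _, L = self.muscle_direction(name, r)
        p = self.params
        return max(0.0, p.pretension
                   + p.stiffness * (L - self._L0[i] + self._gains[i] * u_i))

    # -------------------------------------------------------------- dynamics

    def _engine_args(self):
        p = self.params
        return (self._ins, self._anch, self._L0, self._gains,
                p.stiffness, p.pretension, p.damping)

    def tensions(self, state: EyeState, u) -> np.ndarray:
        u = np.asarray(u, dtype=float).reshape(6)
        tens, _ = _engine.tensions_and_torque(state.r, state.w, u,
                                              *self._engine_args())
        return tens

    def net_torque(self, state: EyeState, u) -> np.ndarray:
        """Net torque (N*mm, head frame): sum of insertion x tension*direction
        over the six tendons, minus viscous damping."""
        u = np.asarray(u, dtype=float).reshape(6)
        _, tau = _engine.tensions_and_torque(state.r, state.w, u,
                                             *self._engine_args())
        return tau

    def step(self, state: EyeState, u) -> EyeState:
        """One semi-implicit Euler step of length ``params.dt``."""
        u = np.asarray(u, dtype=float).reshape(6)
        uu = np.repeat(u[:, None], 2, axis=1)
        rs, ws, _, _ = _engine.simulate_core(uu, state.r, state.w,
                                             *self._engine_args(),
                                             self._inertia, self.params.dt,
                                             self.params.substeps)
        out = EyeState(rs[1], ws[1])
        if not (np.all(np.isfinite(out.r)) and np.all(np.isfinite(out.w))):
            raise FloatingPointError(
                f"plant state diverged (r={out.r}, w={out.w})")
        return out

    def simulate(self, controls, x0: EyeState | None = None) -> Trajectory:
        """Integrate a (6, T) command signal sampled at 1 ms.

        Deterministic: identical (controls, x0, params) give bit-identical
        trajectories.  Raises if the state diverges.
        """
        u = np.asarray(controls, dtype=float)
        if u.ndim != 2 or u.shape[0] != 6:
            raise ValueError("controls must be a (6, T) array")
        if not np.all(np.isfinite(u)):
            raise ValueError("controls must be finite")
        x0 = x0 or EyeState()
        rs, ws, rds, tns = _engine.simulate_core(u, x0.r, x0.w,
                                                 *self._engine_args(),
                                                 self._inertia, self.params.dt,
                                                 self.params.substeps)
        if not np.all(np.isfinite(rs)):
            raise FloatingPointError("plant state diverged during simulation")
        t_ms = np.arange(u.shape[1]) * self.params.dt * 1e3
        return Trajectory(t_ms, rs, ws, rds, tns, u)

    def simulate_rk4(self, controls, x0: EyeState | None = None,
                     substeps: int = 50) -> Trajectory:
        """Classical RK4 reference integration (zero-order-hold commands).

        The velocity dynamics relax on the I/B timescale (~0.03 ms), so the
        explicit reference needs fine substeps to be stable; it is slow and
        exists to validate the default semi-implicit scheme."""
        u = np.asarray(controls, dtype=float)
        x0 = x0 or EyeState()
        dt = self.params.dt / substeps
        T = u.shape[1]
        rs = np.empty((T, 3)); ws = np.empty((T, 3))
        rds = np.empty((T, 3)); tns = np.empty((T, 6))
        r, w = x0.r.copy(), x0.w.copy()
        args = self._engine_args()

        def f(r, w, ut):
            tens, tau = _engine.tensions_and_torque(r, w, ut, *args)
            wdot = _engine._accel(r, w, tau, self._inertia)
            rdot = _engine._rdot_from_omega(r, w)
            return rdot, wdot, tens

        for t in range(T):
            rd, _, tens = f(r, w, u[:, t])
            rs[t], ws[t], rds[t], tns[t] = r, w, rd, tens
            if t == T - 1:
                break
            ut = u[:, t]
            for _ in range(substeps):
                k1r, k1w, _ = f(r, w, ut)
                k2r, k2w, _ = f(r + 0.5 * dt * k1r, w + 0.5 * dt * k1w, ut)
                k3r, k3w, _ = f(r + 0.5 * dt * k2r, w + 0.5 * dt * k2w, ut)
                k4r, k4w, _ = f(r + dt * k3r, w + dt * k3w, ut)
                r = r + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
                w = w + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        t_ms = np.arange(T) * self.params.dt * 1e3
        return Trajectory(t_ms, rs, ws, rds, tns, u)

    # --------------------------------------------------------------- statics

    def solve_fixation_tensions(self, r_fix) -> np.ndarray:
        """Minimum-norm static commands (mm) holding orientation ``r_fix``.

        Torque is linear in the six tensions, so zero net torque at rest is
        three linear constraints on ``u``; the minimum-norm solution is found
        by least squares, falling back to a floor-constrained quadratic
        program if any tendon would drop below the slack floor.
        """
        r_fix = np.asarray(r_fix, dtype=float).reshape(3)
        p = self.params
        # unclamped spring tensions T_pre + k*stretch are the linear
        # baseline; the floor constraint keeps every tendon above slack at
        # the solution, so the zero-clamp never engages there.
        # columns of A: d tau / d u_i = k * gain_i * (p_i x dhat_i)
        from .rotation import rotation_matrix
        R = rotation_matrix(r_fix)
        A = np.empty((3, 6))
        tens0 = np.empty(6)
        tau0 = np.zeros(3)
        for i in range(6):
            pi = R @ self._ins[:, i]
            d = self._anch[:, i] - pi
            L = np.linalg.norm(d)
            tens0[i] = p.pretension + p.stiffness * (L - self._L0[i])
            arm = np.cross(pi, d / L)
            A[:, i] = p.stiffness * self._gains[i] * arm
            tau0 += tens0[i] * arm
        floor = p.tension_floor
        ku = p.stiffness * self._gains
        # active-set iteration: clamp slack-floor violators, re-solve min-norm
        active = np.zeros(6, dtype=bool)
        for _ in range(7):
            u = np.zeros(6)
            u[active] = (floor - tens0[active]) / ku[active]
            free = ~active
            if free.sum() < 3:
                raise RuntimeError(f"no feasible fixation at r={r_fix}")
            rhs = -tau0 - A[:, active] @ u[active]
            uf, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            u[free] = uf
            tens = tens0 + ku * u
            viol = free & (tens < floor - 1e-9)
            if not viol.any():
                break
            active[np.argmin(np.where(free, tens, np.inf))] = True
        else:
            raise RuntimeError(f"no feasible fixation at r={r_fix}")
        if np.linalg.norm(A @ u + tau0) > 1e-6:
            raise RuntimeError(f"fixation torque residual too large at r={r_fix}")
        return u


# ------------------------------------------------------------------ loading


def _build(cfg: dict) -> Plant:
    pc = cfg["params"]
    params = PlantParameters(
        globe_radius=float(cfg["globe_radius_mm"]),
        inertia=tuple(float(v) for v in pc["inertia_kg_mm2"]),
        damping=float(pc["damping_nmm_s_per_rad"]),
        stiffness=float(pc["stiffness_n_per_mm"]),
        pretension=float(pc["pretension_n"]),
        tension_floor=float(pc.get("tension_floor_n", 0.05)),
        dt=float(pc.get("dt_s", 1e-3)),
        substeps=int(pc.get("substeps", 1)),
    )
    muscles = [
        MuscleGeometry(name,
                       np.asarray(m["insertion"], dtype=float),
                       np.asarray(m["anchor"], dtype=float),
                       bool(m.get("pulley", False)),
                       float(m.get("gain", 1.0)))
        for name, m in cfg["muscles"].items()
    ]
    return Plant(muscles, params)


def load_plant(path: str | Path) -> Plant:
    """Build a plant from a YAML geometry/parameter config file."""
    with open(path) as fh:
        return _build(yaml.safe_load(fh))


def default_plant() -> Plant:
    """The packaged default human-like right-eye plant."""
    text = resources.files("bioeye").joinpath("data/default_plant.yaml").read_text()
    return _build(yaml.safe_load(text))
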