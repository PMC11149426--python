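"""Data-generating campaigns: saccade paradigms and muscle stimulation.

Three paradigms populate the saccade datasets:

* ``zero_initial`` -- every saccade starts from straight ahead; 2D goals are
  drawn uniformly over the oculomotor workspace (the disc |(G_y, G_z)| <=
  0.3 rad/2, so amplitudes stay <= ~33 deg and every goal is statically
  holdable by the plant), with G_x = 0.
* ``continuous`` -- goals drawn the same way, but each saccade starts where
  the previous one ended, so amplitudes range up to ~50 deg and initial
  orientations cover the workspace.
* ``horizontal_continuous`` -- purely horizontal chained saccades with goals
  on a discrete grid along the horizontal meridian.

The stimulation experiments mimic electrical microstimulation of a single
muscle: the eye holds an eccentric fixation (in Listing's plane), a Gaussian
command pulse is superposed on the holding command of one muscle, and the
accumulated torsion ``delta r_x = integral rdot_x dt`` is regressed on the
initial eccentricity.  A plant that implemented Listing's law mechanically
would show no position-dependent torsion; this one does not, so the response
is expected to leave the plane linearly in the initial eccentricity, with
opposite slopes for LR vs MR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import rotation
from .analysis import SaccadeMetrics, saccade_metrics
from .control import (ControlParameterization, CostWeights, DEFAULT_WEIGHTS,
                      Goal, optimal_saccade)
from .plant import EyeState, Plant, Trajectory, default_plant

__all__ = [
    "ParadigmConfig",
    "StimulationConfig",
    "SaccadeRecord",
    "SaccadeDataset",
    "StimulationResult",
    "run_paradigm",
    "run_zero_initial",
    "run_continuous",
    "run_horizontal_continuous",
    "stimulate_muscle",
    "stimulate_so",
    "FULL_SCALE_N",
]

PARADIGMS = ("zero_initial", "continuous", "horizontal_continuous")
# published-scale counts per paradigm; desk-scale defaults are below
FULL_SCALE_N = {"zero_initial": 199, "continuous": 298,
                "horizontal_continuous": 202}
DESK_SCALE_N = {"zero_initial": 30, "continuous": 50,
                "horizontal_continuous": 30}


@dataclass(frozen=True)
class ParadigmConfig:
    name: str
    n: int | None = None              # None -> desk-scale default
    goal_radius: float = 0.3          # rad/2, workspace disc radius
    grid_spacing: float = 0.012       # rad/2, horizontal-meridian grid
    seed: int = 0
    maxiter: int = 50
    early_stop: int = 2

    def __post_init__(self):
        if self.name not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.name!r}")
        if self.goal_radius > 0.3 + 1e-9:
            raise ValueError("goal radius outside the +/-0.3 rad/2 range")

    @property
    def n_saccades(self) -> int:
        return self.n if self.n is not None else DESK_SCALE_N[self.name]


@dataclass
class SaccadeRecord:
    """One optimized movement with its provenance and derived metrics."""

    goal: Goal
    start: EyeState
    d_ms: int
    trajectory: Trajectory
    j_mov: float
    j_a: float
    j_d: float
    j_e: float
    amplitude: float                 # deg, angle of the relative rotation
    metrics: SaccadeMetrics


@dataclass
class SaccadeDataset:
    records: list[SaccadeRecord]
    config: ParadigmConfig
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def trajectories(self) -> list[Trajectory]:
        return [r.trajectory for r in self.records]

    @property
    def metrics(self) -> list[SaccadeMetrics]:
        return [r.metrics for r in self.records]

    def all_orientations(self) -> np.ndarray:
        """Pooled (n, 3) rotation-vector samples of every trajectory."""
        return np.vstack([r.trajectory.r for r in self.records])


def _draw_disc_goals(rng, n: int, radius: float) -> np.ndarray:
    """Uniform (G_y, G_z) in the component box, rejecting draws outside the
    workspace disc (keeps every goal statically holdable)."""
    out = np.empty((n, 2))
    k = 0
    while k < n:
        g = rng.uniform(-radius, radius, size=2)
        if np.hypot(*g) <= radius:
            out[k] = g
            k += 1
    return out


def _record(plant: Plant, sac, start: EyeState) -> SaccadeRecord:
    q = rotation.relative_rotation(start.r, sac.goal.r)
    return SaccadeRecord(
        goal=sac.goal, start=start, d_ms=sac.d_ms,
        trajectory=sac.trajectory,
        j_mov=sac.j_mov, j_a=sac.j_a, j_d=sac.j_d, j_e=sac.j_e,
        amplitude=rotation.rotation_angle_deg(q),
        metrics=saccade_metrics(sac.trajectory, duration_ms=sac.d_ms),
    )


def run_paradigm(cfg: ParadigmConfig, plant: Plant | None = None,
                 weights: CostWeights = DEFAULT_WEIGHTS,
                 model=None,
                 param: ControlParameterization = ControlParameterization(),
                 ) -> SaccadeDataset:
    """Run one of the three paradigms; seeded and reproducible."""
    plant = plant or default_plant()
    model = model if model is not None else plant
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_saccades
    if cfg.name == "horizontal_continuous":
        levels = np.arange(-cfg.goal_radius, cfg.goal_radius + 1e-12,
                           cfg.grid_spacing)
        gz = rng.choice(levels, size=n)
        goals = [Goal(0.0, float(g)) for g in gz]
    else:
        gyz = _draw_disc_goals(rng, n, cfg.goal_radius)
        goals = [Goal(float(gy), float(gz)) for gy, gz in gyz]

    chained = cfg.name in ("continuous", "horizontal_continuous")
    records: list[SaccadeRecord] = []
    state = EyeState()
    for i, goal in enumerate(goals):
        start = state.copy() if chained else EyeState()
        sac = optimal_saccade(goal, start, weights, model=model, plant=plant,
                              param=param, maxiter=cfg.maxiter,
                              seed=int(rng.integers(2 ** 31)),
                              early_stop=cfg.early_stop)
        rec = _record(plant, sac, start)
        records.append(rec)
        if chained:
            state = sac.trajectory.final_state
    return SaccadeDataset(records, cfg, cfg.seed)


def run_zero_initial(cfg: ParadigmConfig | None = None, **kw) -> SaccadeDataset:
    return run_paradigm(cfg or ParadigmConfig("zero_initial"), **kw)


def run_continuous(cfg: ParadigmConfig | None = None, **kw) -> SaccadeDataset:
    return run_paradigm(cfg or ParadigmConfig("continuous"), **kw)


def run_horizontal_continuous(cfg: ParadigmConfig | None = None,
                              **kw) -> SaccadeDataset:
    return run_paradigm(cfg or ParadigmConfig("horizontal_continuous"), **kw)


# -------------------------------------------------------------- stimulation


@dataclass(frozen=True)
class StimulationConfig:
    muscle: str = "LR"                 # LR | MR | SO
    width_ms: float = 21.0             # Gaussian pulse full width at half max
    amplitude: float | None = None     # mm; None -> calibrated default
    eccentricities: tuple = tuple(np.round(np.linspace(-0.24, 0.24, 13), 4))
    lp_alpha: float = 0.0              # Listing-plane tilt used for starts
    settle_ms: int = 30
    max_ms: int = 300
    stop_speed_deg_s: float = 1.0      # movement-offset speed threshold

    def __post_init__(self):
        if self.muscle not in ("LR", "MR", "SO"):
            raise ValueError("stimulation supports LR, MR or SO")


@dataclass
class StimulationResult:
    config: StimulationConfig
    eccentricities: np.ndarray     # initial r_y (LR/MR) or r_z (SO), rad/2
    delta_rx: np.ndarray           # accumulated torsion per trial, rad/2
    slope: float
    intercept: float
    r2: float
    trajectories: list[Trajectory] = field(default_factory=list)


def _default_pulse_amplitude(plant: Plant, weights: CostWeights) -> float:
    """Peak agonist drive above its holding level for a 10 deg optimal
    saccade -- a physiologically scaled stimulation strength."""
    g = float(np.tan(np.radians(10.0) / 2.0))
    sac = optimal_saccade(Goal(0.0, -g), EyeState(), weights, model=plant,
                          early_stop=2, maxiter=40, seed=0)
    u_hold = plant.solve_fixation_tensions(np.zeros(3))
    return float(sac.controls[0].max() - u_hold[0])


def stimulate_muscle(cfg: StimulationConfig, plant: Plant | None = None,
                     weights: CostWeights = DEFAULT_WEIGHTS,
                     ) -> StimulationResult:
    """Gaussian-pulse stimulation of one muscle from eccentric fixations.

    For each initial orientation the eye is placed at its Listing-plane
    fixation (r_x = lp_alpha * r_y, holding commands from the static
    solver) and the pulse is superposed on the stimulated muscle's holding
    command.  The accumulated torsion over a fixed response window (pulse
    start to pulse center + ``response_ms``) is regressed on the initial
    eccentricity.
    """
    plant = plant or default_plant()
    amp = cfg.amplitude
    if amp is None:
        amp = _default_pulse_amplitude(plant, weights)
    sigma_ms = cfg.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    idx = {"LR": 0, "MR": 1, "SO": 4}[cfg.muscle]
    onset = cfg.settle_ms + 3.0 * sigma_ms
    tgrid = np.arange(cfg.max_ms + 1, dtype=float)
    pulse = amp * np.exp(-0.5 * ((tgrid - onset) / sigma_ms) ** 2)

    eccs, drx, trajs = [], [], []
    for ecc in cfg.eccentricities:
        if cfg.muscle == "SO":
            r_on = np.array([cfg.lp_alpha * 0.0, 0.0, float(ecc)])
        else:
            r_on = np.array([cfg.lp_alpha * float(ecc), float(ecc), 0.0])
        u_hold = plant.solve_fixation_tensions(r_on)
        u = np.repeat(u_hold[:, None], len(tgrid), axis=1)
        u[idx] += pulse
        traj = plant.simulate(u, EyeState(r_on))
        # response window: pulse start to movement offset, taken as the
        # return of the eye speed below threshold or its first local
        # minimum after the pulse-driven peak -- whichever comes first.
        # (The elastic plant then starts drifting back to the held
        # fixation; integrating through that passive return would cancel
        # the stimulation-induced displacement.)
        speed = np.degrees(np.linalg.norm(traj.w, axis=1))
        start_i = int(cfg.settle_ms)
        pk = int(np.argmax(speed))
        end_i = len(speed) - 1
        for j in range(pk + 1, len(speed) - 1):
            if speed[j] < cfg.stop_speed_deg_s or speed[j + 1] > speed[j]:
                end_i = j
                break
        # delta r_x = integral of rdot_x over the response window
        eccs.append(float(ecc))
        drx.append(float(traj.r[end_i, 0] - traj.r[start_i, 0]))
        trajs.append(traj)

    eccs = np.array(eccs)
    drx = np.array(drx)
    A = np.column_stack([eccs, np.ones_like(eccs)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, drx, rcond=None)
    ss_tot = float(np.sum((drx - drx.mean()) ** 2))
    r2 = 1.0 - float(np.sum((drx - A @ [slope, intercept]) ** 2)) / ss_tot \
        if ss_tot > 0 else 1.0
    return StimulationResult(cfg, eccs, drx, float(slope), float(intercept),
                             float(r2), trajs)


def stimulate_so(cfg: StimulationConfig | None = None,
                 plant: Plant | None = None,
                 weights: CostWeights = DEFAULT_WEIGHTS) -> StimulationResult:
    """SO (trochlear-fiber) stimulation from different horizontal starts;
    the torsion summary is regressed on the initial r_z."""
    if cfg is None:
        cfg = StimulationConfig(muscle="SO")
    elif cfg.muscle != "SO":
        raise ValueError("stimulate_so requires muscle='SO'")
    return stimulate_muscle(cfg, plant, weights)
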