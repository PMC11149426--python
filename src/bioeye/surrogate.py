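"""System identification of the plant: PRBS excitation + recurrent surrogate.

The optimizer can differentiate through the physics simulator directly, but a
cheap input-output approximator of the plant is useful when the simulator is
expensive or external.  Following standard nonlinear ARX practice, the
surrogate predicts the next state change from a tapped delay line of recent
commands and states (optionally augmented with quadratic state features) and
is run closed loop (feeding back its own predictions) at evaluation time.

Training data come from a pseudo-random binary step sequence (PRBS): each
muscle's command switches between two levels at exponentially distributed
hold times, giving a spectrally flat excitation over the band below the
switch rate while covering the mechanical workspace.

The fitted map is linear-in-features (ridge regression), so training is
deterministic given the data and the rollout is a fast numpy loop; the
surrogate satisfies the same ``endpoint(controls, x0)`` protocol the
optimizer uses for the plant hand-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from .plant import EyeState, Plant, Trajectory

__all__ = [
    "PRBSConfig",
    "SurrogateDataset",
    "SurrogateModel",
    "generate_prbs",
    "build_dataset",
    "train_surrogate",
    "rollout",
    "closed_loop_nrmse",
]


@dataclass(frozen=True)
class PRBSConfig:
    """Excitation design: two command levels per muscle, exponential hold
    times (mean ``hold_mean_ms``), total length in ms.  The default desk
    length (2e5 ms) trades fidelity for wall clock; published-scale
    identification used an order of magnitude more."""

    levels: tuple = ((-1.0, 1.0),) * 6   # mm, relative to the holding command
    hold_mean_ms: float = 30.0
    total_ms: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if len(self.levels) != 6:
            raise ValueError("need a (lo, hi) level pair per muscle")
        if self.hold_mean_ms < 1 or self.total_ms < 10:
            raise ValueError("degenerate PRBS configuration")


def generate_prbs(cfg: PRBSConfig, u_hold=None) -> np.ndarray:
    """Seeded (6, T) binary step sequence at 1 ms.

    Each muscle independently alternates between its two levels (offset by
    the holding command ``u_hold`` if given), with i.i.d. exponential hold
    times of mean ``hold_mean_ms`` (floored at 1 ms).
    """
    rng = np.random.default_rng(cfg.seed)
    T = int(cfg.total_ms)
    u = np.empty((6, T))
    base = np.zeros(6) if u_hold is None else np.asarray(u_hold, dtype=float)
    for i in range(6):
        lo, hi = cfg.levels[i]
        level = rng.integers(2)
        t = 0
        while t < T:
            hold = max(1, int(round(rng.exponential(cfg.hold_mean_ms))))
            u[i, t:t + hold] = base[i] + (hi if level else lo)
            level = 1 - level
            t += hold
    return u


@dataclass
class SurrogateDataset:
    """Aligned (u(t), x(t)) -> x(t+1) pairs from a plant run, split into
    contiguous train/validation blocks."""

    u: np.ndarray            # (6, T)
    x: np.ndarray            # (T, 6) = [r, w]
    split: int               # first validation sample index

    @property
    def train(self):
        return self.u[:, :self.split], self.x[:self.split]

    @property
    def validation(self):
        return self.u[:, self.split:], self.x[self.split:]


def build_dataset(prbs: np.ndarray, plant: Plant, x0: EyeState | None = None,
                  val_fraction: float = 0.2) -> SurrogateDataset:
    """Drive the plant with the excitation and package the state sequence."""
    traj = plant.simulate(prbs, x0)
    x = np.hstack([traj.r, traj.w])
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("plant left its numerical range under PRBS")
    split = int(round((1.0 - val_fraction) * x.shape[0]))
    return SurrogateDataset(np.asarray(prbs, dtype=float), x, split)


@dataclass
class SurrogateModel:
    """Ridge NARX surrogate: x(t+1) = x(t) + W @ phi(taps) (z-scored).

    ``n_u``/``n_x`` are the input/output delay-tap counts; ``quadratic``
    appends second-order features -- pairwise products of the current state
    and products of the current command with the current state (the latter
    capture the orientation-dependent muscle action)."""

    n_u: int
    n_x: int
    quadratic: bool
    W: np.ndarray                 # (6, n_features)
    b: np.ndarray                 # (6,)
    mu_f: np.ndarray              # feature normalization
    sd_f: np.ndarray
    sd_y: np.ndarray              # target scaling (per state channel)
    val_nrmse: float = np.nan
    per_channel_nrmse: np.ndarray = field(default_factory=lambda: np.array([]))

    # ------------------------------------------------------------- features

    def _features(self, u_taps: np.ndarray, x_taps: np.ndarray) -> np.ndarray:
        parts = [u_taps.ravel(), x_taps.ravel()]
        if self.quadratic:
            x = x_taps[0]
            u = u_taps[0]
            parts.append(np.outer(x, x)[np.triu_indices(6)])
            parts.append(np.outer(u, x).ravel())
        return np.concatenate(parts)

    def n_features(self) -> int:
        base = 6 * self.n_u + 6 * self.n_x
        return base + (21 + 36 if self.quadratic else 0)

    # -------------------------------------------------------------- rollout

    def endpoint(self, controls: np.ndarray, x0: EyeState):
        xs = self._run(controls, x0)
        return xs[-1, :3], xs[-1, 3:]

    def _run(self, controls: np.ndarray, x0: EyeState) -> np.ndarray:
        u = np.asarray(controls, dtype=float)
        T = u.shape[1]
        xs = np.empty((T, 6))
        xs[0] = np.concatenate([x0.r, x0.w])
        for t in range(T - 1):
            iu = [max(0, t - d) for d in range(self.n_u)]
            ix = [max(0, t - d) for d in range(self.n_x)]
            phi = self._features(u[:, iu].T, xs[ix])
            phin = (phi - self.mu_f) / self.sd_f
            xs[t + 1] = xs[t] + (self.W @ phin + self.b) * self.sd_y
            if not np.all(np.isfinite(xs[t + 1])) or np.abs(xs[t + 1, :3]).max() > 2.0:
                raise FloatingPointError("surrogate rollout diverged")
        return xs


def rollout(model: SurrogateModel, controls: np.ndarray,
            x0: EyeState | None = None) -> Trajectory:
    """Closed-loop surrogate prediction packaged as a Trajectory (tensions
    are not modelled and reported as zeros)."""
    x0 = x0 or EyeState()
    u = np.asarray(controls, dtype=float)
    xs = model._run(u, x0)
    T = u.shape[1]
    from .rotation import orientation_rate_from_omega
    rdot = np.stack([orientation_rate_from_omega(xs[t, :3], xs[t, 3:])
                     for t in range(T)])
    return Trajectory(np.arange(T, dtype=float), xs[:, :3], xs[:, 3:],
                      rdot, np.zeros((T, 6)), u)


def _assemble_targets(ds_u, x_feat, x_true, model: SurrogateModel):
    """Feature rows from (possibly jittered) states, targets from the true
    state increments."""
    T = x_true.shape[0]
    lag = max(model.n_u, model.n_x)
    rows = []
    targets = []
    for t in range(lag - 1, T - 1):
        iu = [t - d for d in range(model.n_u)]
        ix = [t - d for d in range(model.n_x)]
        rows.append(model._features(ds_u[:, iu].T, x_feat[ix]))
        targets.append(x_true[t + 1] - x_true[t])
    return np.asarray(rows), np.asarray(targets)


def train_surrogate(dataset: SurrogateDataset, n_u: int = 2, n_x: int = 2,
                    quadratic: bool = True, alpha: float = 1e-6,
                    state_noise: float = 0.0, seed: int = 0,
                    ) -> SurrogateModel:
    """Fit the ridge NARX map on the training block (teacher forcing) and
    score it by closed-loop NRMSE on the held-out block.

    ``state_noise`` adds seeded Gaussian jitter (in units of each channel's
    sd) to the state taps during fitting -- a standard robustification that
    keeps the closed-loop rollout stable under its own feedback error.
    Raises if the closed-loop validation rollout diverges (training is then
    considered failed)."""
    model = SurrogateModel(n_u, n_x, quadratic,
                           W=np.empty(0), b=np.empty(0), mu_f=np.empty(0),
                           sd_f=np.empty(0), sd_y=np.empty(0))
    u_tr, x_tr = dataset.train
    if state_noise > 0:
        rng = np.random.default_rng(seed)
        x_noisy = x_tr + rng.normal(0.0, state_noise * x_tr.std(axis=0),
                                    x_tr.shape)
    else:
        x_noisy = x_tr
    F, Y = _assemble_targets(u_tr, x_noisy, x_tr, model)
    model.mu_f = F.mean(axis=0)
    model.sd_f = F.std(axis=0)
    model.sd_f[model.sd_f < 1e-12] = 1.0
    model.sd_y = Y.std(axis=0)
    model.sd_y[model.sd_y < 1e-15] = 1.0
    Fn = (F - model.mu_f) / model.sd_f
    Yn = Y / model.sd_y
    reg = Ridge(alpha=alpha, fit_intercept=True).fit(Fn, Yn)
    model.W = reg.coef_
    model.b = reg.intercept_
    u_va, x_va = dataset.validation
    model.per_channel_nrmse, model.val_nrmse = closed_loop_nrmse(
        model, u_va, x_va)
    return model


def closed_loop_nrmse(model: SurrogateModel, u: np.ndarray, x: np.ndarray):
    """Closed-loop (own-feedback) prediction error on a sequence, as RMSE
    per state channel normalized by that channel's sd; returns
    (per-channel, mean).  A diverging rollout propagates as an exception."""
    xs = model._run(u, EyeState(x[0, :3], x[0, 3:]))
    err = xs - x
    rmse = np.sqrt(np.mean(err ** 2, axis=0))
    scale = x.std(axis=0)
    scale[scale < 1e-12] = 1.0
    per = rmse / scale
    return per, float(per.mean())
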