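"""Quantitative analysis of 3D eye movements.

Operates on simulated (or imported) trajectories expressed as
Euler-Rodrigues rotation vectors: saccade metrics (amplitude, direction,
peak velocity), endpoint-accuracy regressions, main-sequence fits and the
saturating amplitude/peak-velocity relation, trajectory curvature,
Listing-plane fits, component cross-coupling against the common-source
model, initial-position gain regressions, and within-saccade muscle-command
correlations.

Gaze angles are in deg (azimuth theta_H = -2 arctan r_z, rightward positive;
elevation phi_V = -2 arctan r_y, upward positive); velocities in deg/s.
Vectorial peak velocity is taken from the angular-velocity norm ||omega||
(switchable to the coordinate velocity); component peak velocities use
gaze-angle derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .plant import MUSCLES, Trajectory

__all__ = [
    "SaccadeMetrics",
    "AccuracyFit",
    "MainSequenceFit",
    "CurvatureResult",
    "ListingPlaneFit",
    "PositionGainFit",
    "SynergyCorrelations",
    "gaze_angles",
    "saccade_metrics",
    "accuracy_regression",
    "main_sequence_fit",
    "predict_vpk",
    "normalize_trajectory",
    "curvature",
    "fit_listing_plane",
    "component_coupling",
    "common_source_prediction",
    "position_gain_regression",
    "synergy_correlations",
    "direction_binned_vpk",
]

# |C| thresholds separating straight / intermediate / really-curved saccades
CURVATURE_STRAIGHT = 0.03
CURVATURE_CURVED = 0.15


def gaze_angles(r: np.ndarray) -> np.ndarray:
    """(T,3) rotation vectors -> (T,2) gaze angles [theta_H, phi_V] in deg."""
    r = np.atleast_2d(np.asarray(r, dtype=float))
    return np.degrees(-2.0 * np.arctan(r[:, [2, 1]]))


# ------------------------------------------------------------------ metrics


@dataclass
class SaccadeMetrics:
    amplitude: float          # R = sqrt(dH^2 + dV^2), deg
    direction: float          # Phi = atan2(dV, dH), deg in (-180, 180]
    duration_ms: float
    v_peak: float             # vectorial peak velocity, deg/s
    v_peak_h: float           # |d theta_H/dt| peak, deg/s
    v_peak_v: float           # |d phi_V/dt| peak, deg/s
    onset: np.ndarray         # gaze angles at movement start (deg)
    offset: np.ndarray        # gaze angles at movement end (deg)
    v_h_signed: float         # signed horizontal component peak (deg/s)


def saccade_metrics(traj: Trajectory, duration_ms: float | None = None,
                    speed_from: str = "omega") -> SaccadeMetrics:
    """Per-saccade kinematic metrics.

    Optimizer-produced saccades span exactly [0, D], so onset/offset are the
    first/last samples and ``duration_ms`` is taken from the optimizer when
    given (else from the trace length).  ``speed_from`` selects the vectorial
    speed definition: the angular-velocity norm (default) or ``"rdot"``.
    """
    ang = gaze_angles(traj.r)
    dh = ang[-1, 0] - ang[0, 0]
    dv = ang[-1, 1] - ang[0, 1]
    amp = float(np.hypot(dh, dv))
    phi = float(np.degrees(np.arctan2(dv, dh)))
    dt = (traj.t_ms[1] - traj.t_ms[0]) / 1e3 if len(traj) > 1 else 1e-3
    if speed_from == "omega":
        speed = np.degrees(np.linalg.norm(traj.w, axis=1))
    elif speed_from == "rdot":
        speed = np.degrees(2.0 * np.linalg.norm(traj.rdot, axis=1))
    else:
        raise ValueError("speed_from must be 'omega' or 'rdot'")
    dang = np.gradient(ang, dt, axis=0)
    ih = int(np.argmax(np.abs(dang[:, 0])))
    d = float(duration_ms) if duration_ms is not None else float(traj.t_ms[-1])
    return SaccadeMetrics(
        amplitude=amp, direction=phi, duration_ms=d,
        v_peak=float(speed.max()),
        v_peak_h=float(np.abs(dang[:, 0]).max()),
        v_peak_v=float(np.abs(dang[:, 1]).max()),
        onset=ang[0], offset=ang[-1],
        v_h_signed=float(dang[ih, 0]),
    )


# ----------------------------------------------------------------- accuracy


@dataclass
class AccuracyFit:
    """Component-wise stimulus-response regressions
    theta_H = a + b T_H and phi_V = c + d T_V (angles in deg)."""

    a: float
    b: float
    c: float
    d: float
    r2_h: float
    r2_v: float
    err_mean: np.ndarray      # (2,) mean signed error, deg
    err_sd: np.ndarray        # (2,) sd of signed error, deg


def _ols(y, X):
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return model


def accuracy_regression(targets_deg: np.ndarray,
                        endpoints_deg: np.ndarray) -> AccuracyFit:
    """OLS of realized vs target gaze components, plus signed-error stats.

    ``targets_deg`` and ``endpoints_deg`` are (n, 2) arrays of
    [theta_H, phi_V] in deg."""
    t = np.asarray(targets_deg, dtype=float)
    e = np.asarray(endpoints_deg, dtype=float)
    if t.shape != e.shape or t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("targets and endpoints must both be (n, 2)")
    mh = _ols(e[:, 0], t[:, 0])
    mv = _ols(e[:, 1], t[:, 1])
    err = e - t
    return AccuracyFit(
        a=float(mh.params[0]), b=float(mh.params[1]),
        c=float(mv.params[0]), d=float(mv.params[1]),
        r2_h=float(mh.rsquared), r2_v=float(mv.rsquared),
        err_mean=err.mean(axis=0), err_sd=err.std(axis=0, ddof=1),
    )


# ------------------------------------------------------------ main sequence


@dataclass
class MainSequenceFit:
    """Affine main-sequence relations D = e + f R and V_PK * D = k + m R.

    Units: e in ms, f in ms/deg, k in deg, m dimensionless (V_PK in deg/s
    and D in s in the second relation).  The combination predicts a peak
    velocity that saturates at m/f (deg/ms) = 1000 m/f deg/s."""

    e: float
    f: float
    k: float
    m: float
    r2_duration: float
    r2_product: float

    @property
    def saturation_velocity(self) -> float:
        """R -> infinity limit of the predicted peak velocity, deg/s."""
        return 1000.0 * self.m / self.f


def main_sequence_fit(amplitudes, durations_ms, v_peaks) -> MainSequenceFit:
    R = np.asarray(amplitudes, dtype=float)
    D = np.asarray(durations_ms, dtype=float)
    V = np.asarray(v_peaks, dtype=float)
    md = _ols(D, R)
    mp = _ols(V * D / 1e3, R)
    return MainSequenceFit(
        e=float(md.params[0]), f=float(md.params[1]),
        k=float(mp.params[0]), m=float(mp.params[1]),
        r2_duration=float(md.rsquared), r2_product=float(mp.rsquared),
    )


def predict_vpk(R, fit: MainSequenceFit) -> np.ndarray:
    """Saturating amplitude/peak-velocity relation implied by the two affine
    main-sequence fits (small offset k ignored so V_PK(0) = 0):

        V_PK(R) = (m/e) / (1/R + f/e)     [deg/s, with e and f in s]
    """
    R = np.asarray(R, dtype=float)
    e_s = fit.e / 1e3
    f_s = fit.f / 1e3
    return (fit.m / e_s) / (1.0 / R + f_s / e_s)


# ---------------------------------------------------------------- curvature


@dataclass
class CurvatureResult:
    c: float
    label: str                # straight | intermediate | curved

    @staticmethod
    def classify(c: float) -> str:
        if abs(c) < CURVATURE_STRAIGHT:
            return "straight"
        if abs(c) > CURVATURE_CURVED:
            return "curved"
        return "intermediate"


def normalize_trajectory(ang_deg: np.ndarray) -> np.ndarray:
    """Translate a planar gaze trace to the origin and rotate its chord onto
    the +x axis:

        theta_rot =  cos(Phi) theta_tr + sin(Phi) phi_tr
        phi_rot   = -sin(Phi) theta_tr + cos(Phi) phi_tr
    """
    a = np.asarray(ang_deg, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise ValueError("trace must be (T >= 2, 2)")
    tr = a - a[0]
    phi = np.arctan2(tr[-1, 1], tr[-1, 0])
    c, s = np.cos(phi), np.sin(phi)
    return tr @ np.array([[c, -s], [s, c]])


def curvature(ang_deg: np.ndarray) -> CurvatureResult:
    """Signed curvature index of a planar trace (after normalization):

        C = -sign(d theta_rot) * phi_rot[argmax |phi_rot|] / |d theta_rot|

    i.e. the largest signed perpendicular deviation from the straight chord,
    normalized by the chord length; clockwise positive.  A rightward
    semicircle with its arc in the first quadrant gives C = -0.5.
    """
    rotn = normalize_trajectory(ang_deg)
    run = rotn[-1, 0]
    if abs(run) < 1e-12:
        raise ValueError("zero-amplitude trace has no curvature")
    peak = rotn[np.argmax(np.abs(rotn[:, 1])), 1]
    c = float(-np.sign(run) * peak / abs(run))
    return CurvatureResult(c, CurvatureResult.classify(c))


# ------------------------------------------------------------ Listing plane


@dataclass
class ListingPlaneFit:
    """Plane r_x = alpha r_y + beta r_z through the instantaneous 3D
    orientation samples (plane through the origin; ordinary LS of r_x on
    (r_y, r_z)).  ``sigma`` is the residual sd in rad/2; ``sigma_deg`` its
    angular equivalent 2 arctan(sigma); ``tilt_deg`` = -arctan(alpha) is the
    rightward rotation about z aligning the plane with the lab frame."""

    alpha: float
    beta: float
    sigma: float
    sigma_deg: float
    tilt_deg: float
    r: float
    n: int


def fit_listing_plane(r_samples: np.ndarray) -> ListingPlaneFit:
    r = np.asarray(r_samples, dtype=float)
    if r.ndim != 2 or r.shape[1] != 3 or r.shape[0] < 3:
        raise ValueError("need (n >= 3, 3) rotation-vector samples")
    X = r[:, 1:3]
    y = r[:, 0]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return ListingPlaneFit(
        alpha=float(coef[0]), beta=float(coef[1]),
        sigma=sigma, sigma_deg=float(np.degrees(2.0 * np.arctan(sigma))),
        tilt_deg=float(np.degrees(-np.arctan(coef[0]))),
        r=float(np.sqrt(max(r2, 0.0))), n=r.shape[0],
    )


# ------------------------------------------------- component cross-coupling


def component_coupling(trajectories: list[Trajectory],
                       metrics: list[SaccadeMetrics],
                       cardinal_margin_deg: float = 20.0) -> pd.DataFrame:
    """Within-saccade correlation of the horizontal and vertical gaze
    velocity profiles, with each saccade labelled oblique (direction at
    least ``cardinal_margin_deg`` away from all cardinal directions) or
    cardinal."""
    rows = []
    for tr, m in zip(trajectories, metrics):
        ang = gaze_angles(tr.r)
        vel = np.gradient(ang, 1e-3, axis=0)
        with np.errstate(invalid="ignore"):
            rho = float(np.corrcoef(vel[:, 0], vel[:, 1])[0, 1])
        dist = np.abs((m.direction % 90.0 + 45.0) % 90.0 - 45.0)
        rows.append({
            "direction": m.direction, "amplitude": m.amplitude,
            "corr_hv": rho,
            "oblique": bool(dist >= cardinal_margin_deg),
        })
    return pd.DataFrame(rows)


def common_source_prediction(component_amp: float, phi_deg,
                             fit: MainSequenceFit,
                             component: str = "h") -> np.ndarray:
    """Common-source (vectorial pulse generator) prediction of a component's
    peak velocity as a function of saccade direction:

        V_PK(dH, Phi) = (m/e) cos(Phi) / (1/dH + f/e)
        V_PK(dV, Phi) = (m/e) sin(Phi) / (1/dV + f/e)

    No free parameters beyond the global main-sequence fit.  At Phi = 0 the
    horizontal form reduces to the vectorial saturating relation."""
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    e_s = fit.e / 1e3
    f_s = fit.f / 1e3
    trig = np.cos(phi) if component == "h" else np.sin(phi)
    return (fit.m / e_s) * trig / (1.0 / component_amp + f_s / e_s)


# ------------------------------------------------------ position-gain model


@dataclass
class PositionGainFit:
    """Nested z-scored regressions of peak velocity on amplitude alone and
    on amplitude + initial eccentricity (all variables standardized):

        V^ = g_R1 dH^          and        V^ = g_R2 dH^ + g_Hon H_on^

    ``h_on`` is the initial orientation component along the movement,
    sign-flipped so that positive means starting contralateral to the
    movement direction."""

    g_r1: float
    g_r2: float
    g_hon: float
    r2_amp: float
    r2_full: float
    f_pvalue: float
    n: int
    means: dict
    sds: dict


def position_gain_regression(amplitudes, h_on, v_peaks,
                             min_amplitude_deg: float = 6.0) -> PositionGainFit:
    """Quantify the initial-position dependence of horizontal peak velocity.

    ``amplitudes``: signed horizontal displacement dH (deg); ``h_on``:
    initial horizontal orientation (deg, rightward positive); ``v_peaks``:
    peak velocity magnitude (deg/s).  Only movements with |dH| >=
    ``min_amplitude_deg`` enter (peak velocity is nearly linear in amplitude
    there).  Significance of the added position regressor is assessed with a
    nested-model F test."""
    dh = np.asarray(amplitudes, dtype=float)
    hon = np.asarray(h_on, dtype=float)
    v = np.asarray(v_peaks, dtype=float)
    keep = np.abs(dh) >= min_amplitude_deg
    if keep.sum() < 5:
        raise ValueError("too few saccades above the amplitude cutoff")
    amp = np.abs(dh[keep])
    contra = -np.sign(dh[keep]) * hon[keep]
    vpk = np.abs(v[keep])
    cols = {"amp": amp, "contra": contra, "v": vpk}
    for name, x in cols.items():
        if np.std(x) < 1e-12:
            raise ValueError(f"zero-variance regressor '{name}'")
    z = {k: (x - x.mean()) / x.std(ddof=1) for k, x in cols.items()}
    m1 = sm.OLS(z["v"], z["amp"]).fit()
    m2 = sm.OLS(z["v"], np.column_stack([z["amp"], z["contra"]])).fit()
    f_test = m2.compare_f_test(m1)
    return PositionGainFit(
        g_r1=float(m1.params[0]), g_r2=float(m2.params[0]),
        g_hon=float(m2.params[1]),
        r2_amp=float(m1.rsquared), r2_full=float(m2.rsquared),
        f_pvalue=float(f_test[1]), n=int(keep.sum()),
        means={k: float(x.mean()) for k, x in cols.items()},
        sds={k: float(x.std(ddof=1)) for k, x in cols.items()},
    )


# ----------------------------------------------------------- synergies etc.


SYNERGY_PAIRS = (("LR", "MR"), ("SR", "IR"), ("SO", "IO"),
                 ("SR", "IO"), ("SO", "IR"))


@dataclass
class SynergyCorrelations:
    per_saccade: pd.DataFrame     # one row per saccade, one column per pair

    def median(self, pair: tuple[str, str]) -> float:
        return float(self.per_saccade[f"{pair[0]}-{pair[1]}"].median())


def synergy_correlations(trajectories: list[Trajectory],
                         pairs=SYNERGY_PAIRS) -> SynergyCorrelations:
    """Within-saccade Pearson correlations between muscle-command pairs.

    Agonist pairs are expected near +1, antagonist pairs near -1; commands
    are used relative to their starting (pretension-holding) level."""
    idx = {n: i for i, n in enumerate(MUSCLES)}
    rows = []
    for tr in trajectories:
        row = {}
        for a, b in pairs:
            ua = tr.u[idx[a]] - tr.u[idx[a], 0]
            ub = tr.u[idx[b]] - tr.u[idx[b], 0]
            sa, sb = ua.std(), ub.std()
            if sa < 1e-12 or sb < 1e-12:
                row[f"{a}-{b}"] = np.nan
            else:
                row[f"{a}-{b}"] = float(np.corrcoef(ua, ub)[0, 1])
        rows.append(row)
    return SynergyCorrelations(pd.DataFrame(rows))


def direction_binned_vpk(metrics: list[SaccadeMetrics],
                         amplitude_bins=(0.0, 10.0, 20.0, 30.0, 50.0),
                         direction_bin_deg: float = 30.0) -> pd.DataFrame:
    """Mean +/- sd of vectorial peak velocity in direction x amplitude bins."""
    df = pd.DataFrame({
        "amplitude": [m.amplitude for m in metrics],
        "direction": [m.direction % 360.0 for m in metrics],
        "v_peak": [m.v_peak for m in metrics],
    })
    df["amp_bin"] = pd.cut(df["amplitude"], amplitude_bins)
    edges = np.arange(-direction_bin_deg / 2, 360.0 + direction_bin_deg / 2,
                      direction_bin_deg)
    centered = (df["direction"] + direction_bin_deg / 2) % 360.0 - direction_bin_deg / 2
    df["dir_bin"] = pd.cut(centered, edges)
    out = (df.groupby(["amp_bin", "dir_bin"], observed=True)["v_peak"]
             .agg(["mean", "std", "count"]).reset_index())
    return out
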