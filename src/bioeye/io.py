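"""File formats and reproducibility plumbing.

Trajectories are stored as plain CSV (one row per 1 ms sample) with a fixed
column order and a unit header comment, losslessly round-tripping at 1e-9.
Saccade datasets are directories of trajectory CSVs plus a ``manifest.json``
carrying per-record provenance (goal, start, duration, costs, metrics) and
the config snapshot, so a run can be re-executed or re-analyzed exactly.
A single master seed fans out to per-stage seeds through numpy's
SeedSequence spawning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .control import Goal
from .plant import EyeState, MUSCLES, Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectory",
    "read_trajectory",
    "write_dataset",
    "read_dataset",
    "spawn_seeds",
    "config_hash",
]

TRAJECTORY_COLUMNS = (
    ["t_ms", "rx", "ry", "rz", "wx", "wy", "wz"]
    + [f"u_{m}" for m in MUSCLES] + [f"T_{m}" for m in MUSCLES]
)

_UNITS_HEADER = (
    "# t_ms [ms]; rx..rz [rad/2, Euler-Rodrigues]; wx..wz [rad/s];"
    " u_* [mm commanded shortening]; T_* [N tendon tension]"
)


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        np.column_stack([traj.t_ms, traj.r, traj.w, traj.u.T, traj.tensions]),
        columns=TRAJECTORY_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path}: unexpected trajectory schema {list(df.columns)}")
    u = df[[f"u_{m}" for m in MUSCLES]].to_numpy().T
    tens = df[[f"T_{m}" for m in MUSCLES]].to_numpy()
    r = df[["rx", "ry", "rz"]].to_numpy()
    w = df[["wx", "wy", "wz"]].to_numpy()
    from .rotation import orientation_rate_from_omega
    rdot = np.stack([orientation_rate_from_omega(r[t], w[t])
                     for t in range(r.shape[0])])
    return Trajectory(df["t_ms"].to_numpy(), r, w, rdot, tens, u)


# ----------------------------------------------------------------- datasets


def write_dataset(dataset, outdir) -> Path:
    """Persist a SaccadeDataset as trajectory CSVs + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(dataset.records):
        fname = f"saccade_{i:04d}.csv"
        write_trajectory(rec.trajectory, outdir / fname)
        entries.append({
            "file": fname,
            "goal": [rec.goal.gy, rec.goal.gz],
            "start_r": rec.start.r.tolist(),
            "start_w": rec.start.w.tolist(),
            "d_ms": rec.d_ms,
            "costs": {"j_mov": rec.j_mov, "j_a": rec.j_a,
                      "j_d": rec.j_d, "j_e": rec.j_e},
            "amplitude_deg": rec.amplitude,
            "metrics": {
                "amplitude": rec.metrics.amplitude,
                "direction": rec.metrics.direction,
                "duration_ms": rec.metrics.duration_ms,
                "v_peak": rec.metrics.v_peak,
                "v_peak_h": rec.metrics.v_peak_h,
                "v_peak_v": rec.metrics.v_peak_v,
            },
        })
    manifest = {
        "paradigm": dataset.config.name,
        "seed": dataset.seed,
        "config": dataclasses.asdict(dataset.config),
        "n_records": len(dataset.records),
        "records": entries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def read_dataset(indir):
    """Reload a stored dataset (trajectories + provenance).

    Returns a :class:`~bioeye.experiments.SaccadeDataset`; metrics are taken
    from the manifest snapshot."""
    from .analysis import SaccadeMetrics, gaze_angles
    from .experiments import ParadigmConfig, SaccadeDataset, SaccadeRecord

    indir = Path(indir)
    mpath = indir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {indir}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest["n_records"] == 0:
        raise ValueError(f"dataset in {indir} is empty")
    cfg = ParadigmConfig(**manifest["config"])
    records = []
    for e in manifest["records"]:
        traj = read_trajectory(indir / e["file"])
        ang = gaze_angles(traj.r)
        met = SaccadeMetrics(
            amplitude=e["metrics"]["amplitude"],
            direction=e["metrics"]["direction"],
            duration_ms=e["metrics"]["duration_ms"],
            v_peak=e["metrics"]["v_peak"],
            v_peak_h=e["metrics"]["v_peak_h"],
            v_peak_v=e["metrics"]["v_peak_v"],
            onset=ang[0], offset=ang[-1],
            v_h_signed=np.nan,
        )
        records.append(SaccadeRecord(
            goal=Goal(*e["goal"]),
            start=EyeState(np.array(e["start_r"]), np.array(e["start_w"])),
            d_ms=e["d_ms"], trajectory=traj,
            j_mov=e["costs"]["j_mov"], j_a=e["costs"]["j_a"],
            j_d=e["costs"]["j_d"], j_e=e["costs"]["j_e"],
            amplitude=e["amplitude_deg"], metrics=met))
    return SaccadeDataset(records, cfg, manifest["seed"])


# ------------------------------------------------------------ reproducibility


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out to ``n`` independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable config snapshot."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
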