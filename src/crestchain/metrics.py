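"""Trajectory metrics shared by in-vivo track tables and simulations.

Works on tidy track tables (one row per cell per frame, columns
``cell_id, identity, frame, t_min, x_um, y_um, z_um``) as produced by
5-minute-interval live imaging or exported from the simulator.

Metric conventions:

* speed between consecutive frames is the 3D displacement divided by the
  frame interval in minutes, times 60 (um/hr) — exactly the tracking
  formula used for the in-vivo data; a cell's ``mean_speed`` is the mean
  of these per-step speeds;
* directionality is net displacement over total path length (in [0, 1],
  1 for a straight monotone path), computed in 3D;
* ventral distance is the straight-line dorsoventral distance from the
  dorsal edge to the cell's final position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Identity, Trajectory
from .scoring import ScoreConfig, detect_overtakings

__all__ = [
    "MetricsConfig",
    "instantaneous_speed",
    "track_speeds",
    "directionality",
    "ventral_distance",
    "summarize",
    "trajectory_to_track_table",
]

TRACK_COLUMNS = ["cell_id", "identity", "frame", "t_min", "x_um", "y_um", "z_um"]


@dataclass(frozen=True)
class MetricsConfig:
    dorsal_edge_y: float = 0.0
    overtake_delta: float = 2.0
    overtake_min_frames: int = 3


def instantaneous_speed(p1, p2, T: float) -> float:
    """Speed in um/hr between two 3D positions T minutes apart."""
    if T <= 0:
        raise ValueError("T must be > 0 minutes")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(
        (np.sqrt(((p1 - p2) ** 2).sum()) / T) * 60.0
    )


def track_speeds(xyz: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Per-step speeds (um/hr) along one cell's track."""
    xyz = np.asarray(xyz, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    disp = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    dt = np.diff(t_min)
    if np.any(dt <= 0):
        raise ValidationError("track times must be strictly increasing")
    return disp / dt * 60.0


def directionality(xyz: np.ndarray) -> float:
    """Net displacement / total path length; NaN for a zero-length path."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[0] < 2:
        raise ValidationError("directionality needs at least two frames")
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    path = float(steps.sum())
    if path == 0:
        return float("nan")
    net = float(np.linalg.norm(xyz[-1] - xyz[0]))
    return net / path


def ventral_distance(y: np.ndarray, dorsal_edge_y: float = 0.0) -> float:
    """Final dorsoventral position relative to the dorsal edge (um)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("empty track")
    return float(y[-1] - dorsal_edge_y)


def trajectory_to_track_table(traj: Trajectory) -> pd.DataFrame:
    """Export a simulated Trajectory as a tidy track table (z_um = 0)."""
    frames, cells = traj.n_frames, traj.n_cells
    rows = {
        "cell_id": np.repeat([f"cell{k:03d}" for k in range(cells)], frames),
        "identity": np.repeat([i.value for i in traj.identities], frames),
        "frame": np.tile(np.arange(frames), cells),
        "t_min": np.tile(traj.times, cells),
        "x_um": traj.positions[:, :, 0].T.ravel(),
        "y_um": traj.positions[:, :, 1].T.ravel(),
        "z_um": np.zeros(frames * cells),
    }
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def _table_to_trajectory(table: pd.DataFrame) -> Trajectory:
    """Internal: pivot a track table into a Trajectory for overtaking."""
    cells = list(dict.fromkeys(table["cell_id"]))
    frames = np.sort(table["frame"].unique())
    n_f, n_c = len(frames), len(cells)
    pos = np.full((n_f, n_c, 2), np.nan)
    identities = []
    times = None
    for k, cid in enumerate(cells):
        sub = table[table["cell_id"] == cid].sort_values("frame")
        idx = np.searchsorted(frames, sub["frame"].to_numpy())
        pos[idx, k, 0] = sub["x_um"].to_numpy()
        pos[idx, k, 1] = sub["y_um"].to_numpy()
        identities.append(Identity(sub["identity"].iloc[0]))
        if times is None or len(sub) == n_f:
            times = sub["t_min"].to_numpy()
    return Trajectory(
        positions=pos,
        identities=tuple(identities),
        times=times,
        radii=np.ones(n_c),
    )


def summarize(
    table: pd.DataFrame, cfg: MetricsConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-cell metrics and per-identity aggregates.

    Returns a per-cell frame (cell_id, identity, mean_speed, directionality,
    ventral_distance, final_x, final_y, overtaker) and an aggregate dict with
    per-identity means/SDs.  When the table carries a constant per-cell
    ``area_um2`` column, the aggregate includes the leader/follower
    mean-area ratio.
    """
    cfg = cfg or MetricsConfig()
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"track table missing columns: {missing}")

    score_cfg = ScoreConfig(
        overtake_delta=cfg.overtake_delta, overtake_min_frames=cfg.overtake_min_frames
    )
    complete = table.groupby("cell_id")["frame"].count().nunique() == 1
    overtakers: set = set()
    if complete and table["cell_id"].nunique() >= 2:
        traj = _table_to_trajectory(table)
        events = detect_overtakings(traj, score_cfg)
        cells = list(dict.fromkeys(table["cell_id"]))
        overtakers = {cells[j] for j in events["overtakers"]}

    records = []
    for cid, sub in table.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        xyz = sub[["x_um", "y_um", "z_um"]].to_numpy()
        t = sub["t_min"].to_numpy()
        records.append(
            {
                "cell_id": cid,
                "identity": sub["identity"].iloc[0],
                "mean_speed": float(np.mean(track_speeds(xyz, t))) if len(sub) > 1 else np.nan,
                "directionality": directionality(xyz) if len(sub) > 1 else np.nan,
                "ventral_distance": ventral_distance(sub["y_um"].to_numpy(), cfg.dorsal_edge_y),
                "final_x": float(sub["x_um"].iloc[-1]),
                "final_y": float(sub["y_um"].iloc[-1]),
                "overtaker": cid in overtakers,
            }
        )
        if "area_um2" in sub.columns:
            records[-1]["area_um2"] = float(sub["area_um2"].iloc[0])
    per_cell = pd.DataFrame(records)

    aggregates: dict = {"identities": {}}
    metric_cols = ["mean_speed", "directionality", "ventral_distance"]
    if "area_um2" in per_cell.columns:
        metric_cols.append("area_um2")
    for ident, sub in per_cell.groupby("identity"):
        if len(sub) == 0:
            continue
        aggregates["identities"][ident] = {
            "n": int(len(sub)),
            **{
                m: {"mean": float(sub[m].mean()), "sd": float(sub[m].std(ddof=1))}
                for m in metric_cols
            },
        }
    if "area_um2" in per_cell.columns:
        by_ident = per_cell.groupby("identity")["area_um2"].mean()
        if "leader" in by_ident.index and "follower" in by_ident.index:
            aggregates["area_ratio_leader_over_follower"] = float(
                by_ident["leader"] / by_ident["follower"]
            )
    return per_cell, aggregates
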