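"""Readers/writers for the package's CSV and JSON formats.

CSV dialect: UTF-8, comma separated, ``.`` decimal, header required.
Track tables use the strict header ``cell_id,identity,frame,t_min,x_um,
y_um,z_um`` with unit suffixes asserted by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import TRACK_COLUMNS, trajectory_to_track_table
from .model import Arena, Identity, ModelParams, Trajectory

__all__ = [
    "read_track_table",
    "write_track_table",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "save_trajectory",
    "load_trajectory",
    "write_json",
    "read_json",
    "RunManifest",
    "read_sequences_csv",
    "write_sequences_csv",
]


def read_track_table(path) -> pd.DataFrame:
    """Read and validate a tidy track table CSV.

    Checks the strict header, duplicate (cell_id, frame) rows, strictly
    increasing frames with a constant interval per cell, and a constant
    identity per cell; violations raise ValidationError naming rows.
    """
    table = pd.read_csv(path)
    if list(table.columns) != TRACK_COLUMNS:
        raise ValidationError(
            f"expected header {TRACK_COLUMNS}, got {list(table.columns)}"
        )
    dup = table.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        rows = list(np.flatnonzero(dup)[:5])
        raise ValidationError(f"duplicated (cell_id, frame) at rows {rows}")
    for cid, sub in table.groupby("cell_id"):
        frames = sub["frame"].to_numpy()
        diffs = np.diff(frames)
        if np.any(diffs <= 0):
            bad = sub.index[1:][diffs <= 0][0]
            raise ValidationError(
                f"non-increasing frames for cell {cid!r} at row {bad}"
            )
        t = sub["t_min"].to_numpy()
        dts = np.diff(t)
        if len(dts) and not np.allclose(dts, dts[0]):
            raise ValidationError(f"inconsistent frame interval for cell {cid!r}")
        if sub["identity"].nunique() != 1:
            raise ValidationError(f"identity changes within cell {cid!r}")
        for ident in sub["identity"].unique():
            Identity(ident)  # raises on unknown labels
    return table


def write_track_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"track table missing columns: {missing}")
    table[TRACK_COLUMNS].to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Export a Trajectory in the shared track-table CSV format."""
    write_track_table(trajectory_to_track_table(traj), path)


def read_trajectory_csv(path, radii=None) -> Trajectory:
    """Rebuild a Trajectory from a track-table CSV of a complete grid."""
    table = read_track_table(path)
    cells = list(dict.fromkeys(table["cell_id"]))
    frames = np.sort(table["frame"].unique())
    pos = np.empty((len(frames), len(cells), 2))
    identities = []
    for k, cid in enumerate(cells):
        sub = table[table["cell_id"] == cid].sort_values("frame")
        if len(sub) != len(frames):
            raise ValidationError(f"cell {cid!r} missing frames")
        pos[:, k, 0] = sub["x_um"].to_numpy()
        pos[:, k, 1] = sub["y_um"].to_numpy()
        identities.append(Identity(sub["identity"].iloc[0]))
    times = np.sort(table["t_min"].unique())
    if radii is None:
        params = ModelParams()
        radii = np.array([params.cell_radius[i] for i in identities])
    return Trajectory(
        positions=pos,
        identities=tuple(identities),
        times=times,
        radii=np.asarray(radii, dtype=float),
    )


def save_trajectory(traj: Trajectory, path) -> None:
    """Binary array container for a Trajectory (npz)."""
    np.savez_compressed(
        path,
        positions=traj.positions,
        times=traj.times,
        radii=traj.radii,
        identities=np.array([i.value for i in traj.identities]),
        seed=np.array(-1 if traj.seed is None else traj.seed),
    )


def load_trajectory(path) -> Trajectory:
    data = np.load(path, allow_pickle=False)
    seed = int(data["seed"])
    return Trajectory(
        positions=data["positions"],
        times=data["times"],
        radii=data["radii"],
        identities=tuple(Identity(str(s)) for s in data["identities"]),
        seed=None if seed < 0 else seed,
    )


def write_sequences_csv(sequences, path) -> None:
    """Phase-state sequences as a long CSV (cell_id, identity, frame, label, onset)."""
    rows = []
    for seq in sequences:
        for t, lab in enumerate(seq.labels):
            rows.append(
                {
                    "cell_id": seq.cell_id,
                    "identity": seq.identity,
                    "frame": t,
                    "label": lab,
                    "onset": int(seq.onset_frame == t)
                    if seq.onset_frame is not None
                    else 0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sequences_csv(path, frame_interval: float = 5.0):
    from .cellcycle import PhaseStateSequence

    table = pd.read_csv(path)
    required = ["cell_id", "identity", "frame", "label"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"sequence table missing columns: {missing}")
    sequences = []
    for cid, sub in table.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        onset = None
        if "onset" in sub.columns and (sub["onset"] == 1).any():
            onset = int(sub.loc[sub["onset"] == 1, "frame"].iloc[0])
        sequences.append(
            PhaseStateSequence(
                cell_id=str(cid),
                identity=str(sub["identity"].iloc[0]),
                labels=[str(x) for x in sub["label"]],
                frame_interval=frame_interval,
                onset_frame=onset,
            )
        )
    return sequences


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, Identity):
            return o.value
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, cls=_JSONEncoder, indent=2, sort_keys=True) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())


@dataclasses.dataclass
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    command: str
    config_hash: str
    master_seed: int
    package_version: str
    inputs: list[str]
    outputs: list[str]
    timestamp: str = ""

    @classmethod
    def create(cls, command, config, master_seed, inputs, outputs):
        from . import __version__

        payload = json.dumps(config, sort_keys=True, cls=_JSONEncoder)
        return cls(
            command=command,
            config_hash=hashlib.sha256(payload.encode()).hexdigest(),
            master_seed=master_seed,
            package_version=__version__,
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, out_dir) -> None:
        write_json(dataclasses.asdict(self), Path(out_dir) / "manifest.json")
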