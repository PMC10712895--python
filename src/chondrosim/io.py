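"""Snapshot, event-log and VTK output helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import KIND_NAME
from .engine import Trajectory

__all__ = [
    "snapshot_frame",
    "trajectory_to_csv",
    "events_to_frame",
    "write_vtk_series",
    "load_points_csv",
]


def snapshot_frame(snap: dict) -> pd.DataFrame:
    """One trajectory snapshot as a tidy cell table."""
    return pd.DataFrame(
        {
            "t": snap["t"],
            "cell_id": snap["cell_id"],
            "clone_id": snap["clone_id"],
            "kind": [KIND_NAME[int(k)] for k in snap["kind"]],
            "activated": snap["activated"],
            "x": snap["x"],
            "y": snap["y"],
            "z": snap["z"],
        }
    )


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Write the full snapshot series as one long-format CSV."""
    frames = [snapshot_frame(s) for s in traj.snapshots]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def events_to_frame(traj: Trajectory) -> pd.DataFrame:
    rows = [
        {
            "time": ev.time,
            "step": ev.step,
            "mother_id": ev.mother_id,
            "mother_kind": ev.mother_kind,
            "clone_id": ev.clone_id,
            "daughter_id_1": ev.daughter_ids[0],
            "daughter_id_2": ev.daughter_ids[1],
            "dir_x": ev.direction[0],
            "dir_y": ev.direction[1],
            "dir_z": ev.direction[2],
            "mother_x": ev.mother_position[0],
            "mother_y": ev.mother_position[1],
            "mother_z": ev.mother_position[2],
        }
        for ev in traj.events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "time", "step", "mother_id", "mother_kind", "clone_id",
            "daughter_id_1", "daughter_id_2", "dir_x", "dir_y", "dir_z",
            "mother_x", "mother_y", "mother_z",
        ],
    )


def _write_vtk_points(snap: dict, path: Path) -> None:
    # legacy VTK ASCII point cloud with clone_id and kind as point data
    n = len(snap["x"])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cell midpoints at t={float(snap['t'][0]) if n else 0.0:.4f}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for x, y, z in zip(snap["x"], snap["y"], snap["z"]):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS clone_id int 1\nLOOKUP_TABLE default\n")
        for c in snap["clone_id"]:
            fh.write(f"{int(c)}\n")
        fh.write("SCALARS kind int 1\nLOOKUP_TABLE default\n")
        for k in snap["kind"]:
            fh.write(f"{int(k)}\n")


def write_vtk_series(traj: Trajectory, out_dir) -> list[Path]:
    """One legacy-VTK point file per snapshot, for 3D viewing."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, snap in enumerate(traj.snapshots):
        path = out_dir / f"snapshot_{i:04d}.vtk"
        _write_vtk_points(snap, path)
        paths.append(path)
    return paths


def load_points_csv(path) -> pd.DataFrame:
    """Load an external point+lineage table (clone_id, x, y[, z]) for scoring."""
    df = pd.read_csv(path)
    missing = {"clone_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    return df
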