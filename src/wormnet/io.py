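"""Readers and writers for the package's text and image dialects.

Trajectories and tracks travel as delimited text with self-describing
headers; image stacks travel as multi-page TIFF or directories of
numbered PNG frames.  Every writer/reader pair round-trips within print
precision, and every run can drop a provenance record (full
configuration + package version) next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import ActivitySchedule, ModelParams, ParticleState, Trajectory
from .estimation import TrackSet

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_tracks",
    "read_tracks",
    "write_frames",
    "read_frames",
    "write_provenance",
]

_TRAJ_COLUMNS = ["t", "particle_id", "x", "y", "theta", "omega", "active"]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a commented-header delimited text table."""
    path = Path(path)
    if len(traj.states) == 0:
        raise ValueError("refusing to write an empty trajectory")
    p = traj.params
    meta = {
        "k_a": p.k_a, "k_r": p.k_r, "r_r": p.r_r,
        "omega0": p.omega0, "sigma_omega": p.sigma_omega, "tau": p.tau,
        "dt": p.dt, "box_side": p.box_side, "n_particles": p.n,
        "seed": p.seed, "delta_out": traj.delta_out,
        "schedule": list(traj.schedule.intervals),
    }
    with open(path, "w") as fh:
        fh.write("# wormnet trajectory v1\n")
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("\t".join(_TRAJ_COLUMNS) + "\n")
        for st in traj.states:
            ids = np.arange(st.n)
            block = np.column_stack(
                [np.full(st.n, st.t), ids, st.x, st.y, st.theta, st.omega,
                 st.active]
            )
            np.savetxt(fh, block, delimiter="\t",
                       fmt=["%.6f", "%d", "%.9g", "%.9g", "%.9g", "%.9g", "%d"])


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline()
        if not magic.startswith("# wormnet trajectory"):
            raise ValueError(f"{path}: not a wormnet trajectory file")
        meta = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh, sep="\t")
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    schedule = ActivitySchedule(tuple(tuple(iv) for iv in meta.pop("schedule")))
    delta_out = meta.pop("delta_out")
    meta["n_particles"] = int(meta["n_particles"])
    meta["seed"] = int(meta["seed"])
    params = ModelParams(**meta)
    traj = Trajectory(params=params, delta_out=delta_out, schedule=schedule)
    for t_val, grp in df.groupby("t", sort=True):
        grp = grp.sort_values("particle_id")
        if len(grp) != params.n:
            raise ValueError(
                f"{path}: snapshot t={t_val} has {len(grp)} rows, "
                f"expected {params.n}"
            )
        traj.states.append(
            ParticleState(
                float(t_val),
                grp["x"].to_numpy(), grp["y"].to_numpy(),
                grp["theta"].to_numpy(), grp["omega"].to_numpy(),
                grp["active"].to_numpy(dtype=float),
            )
        )
    return traj


def write_tracks(tracks: TrackSet, path) -> None:
    """Write centroid tracks as (animal_id, frame, x_um, y_um) text."""
    n, m, _ = tracks.positions.shape
    rows = {
        "animal_id": np.repeat(list(tracks.ids), m),
        "frame": np.tile(np.arange(m), n),
        "x_um": tracks.positions[:, :, 0].ravel(),
        "y_um": tracks.positions[:, :, 1].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_tracks(path, dt: float) -> TrackSet:
    """Read centroid tracks; frames must be uniform and gap-free per animal.

    Row order is irrelevant (rows are sorted by frame); a missing or
    duplicated frame inside any track raises a named error.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    lengths = df.groupby("animal_id").size()
    if lengths.nunique() != 1:
        raise ValueError(
            f"{path}: unequal track lengths {sorted(lengths.unique())}"
        )
    m = int(lengths.iloc[0])
    ids, blocks = [], []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        expect = np.arange(frames[0], frames[0] + m)
        if not np.array_equal(frames, expect):
            raise ValueError(
                f"{path}: animal {aid!r} has missing/duplicate frames "
                "(tracks must be gap-free at uniform sampling)"
            )
        ids.append(aid)
        blocks.append(grp[["x_um", "y_um"]].to_numpy())
    return TrackSet(np.stack(blocks), dt, ids=tuple(ids))


def write_frames(frames: np.ndarray, path) -> None:
    """Write an image stack: multi-page TIFF (.tif) or numbered PNGs (dir)."""
    frames = np.asarray(frames)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, frames)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{k:05d}.png", frame)


def read_frames(path) -> np.ndarray:
    """Read an image stack written by :func:`write_frames` (order preserved)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise ValueError(f"{path}: no frame_*.png files found")
        frames = [iio.imread(f) for f in files]
    else:
        arr = tifffile.imread(path)
        frames = [arr] if arr.ndim == 2 else list(arr)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"{path}: mixed frame dimensions {sorted(shapes)}")
    return np.stack(frames)


def write_provenance(path, config: dict) -> None:
    """Drop a provenance record (config + version) beside run outputs."""
    from . import __version__

    record = {"wormnet_version": __version__, "config": config}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
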