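"""Serialization of trajectories and diagnostics.

Trajectories go to an HDF5 container (layout: /theta snapshots, /time,
/params attributes including the code version, config hash and seeds);
scalar diagnostics go to CSV with a header row.  A plain ``.npy`` dump of a
single field is provided as a lightweight fixture fallback.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .integrate import Trajectory
from .model import DirectorField

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_field",
    "load_field",
    "msv_frame",
    "write_msv_csv",
    "write_kymograph_csv",
]


def save_trajectory(path: str | Path, traj: Trajectory,
                    config_hash: str = "", seed=None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        f.attrs["config_hash"] = config_hash
        f.attrs["time_unit"] = traj.time_unit
        if seed is not None:
            f.attrs["seed"] = seed
        for k, v in traj.params.items():
            if v is None:
                continue
            if isinstance(v, dict):
                for kk, vv in v.items():
                    if vv is not None:
                        f.attrs[f"{k}_{kk}"] = vv
            else:
                f.attrs[k] = v
        d = f.create_group("diagnostics")
        d.create_dataset("time", data=traj.times)
        d.create_dataset("msv", data=traj.msv)
        d.create_dataset("msv_x", data=traj.msv_x)
        d.create_dataset("msv_y", data=traj.msv_y)
        if traj.snapshots:
            s = f.create_group("snapshots")
            s.create_dataset("time", data=np.asarray(traj.snapshot_times))
            s.create_dataset("theta", data=np.stack(traj.snapshots))
        if traj.final is not None:
            f.create_dataset("theta", data=traj.final.theta)
            f.attrs["final_time"] = traj.final.time


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        d = f["diagnostics"]
        msv_x = d["msv_x"][:]
        msv_y = d["msv_y"][:]
        snaps, snap_t = [], []
        if "snapshots" in f:
            snap_t = list(f["snapshots/time"][:])
            snaps = list(f["snapshots/theta"][:])
        final = None
        if "theta" in f:
            final = DirectorField(f["theta"][:], float(f.attrs.get("final_time", 0.0)))
        params = {k: f.attrs[k] for k in f.attrs
                  if k not in ("version", "config_hash", "time_unit", "seed",
                               "final_time")}
        return Trajectory(times=d["time"][:], msv=d["msv"][:], msv_x=msv_x,
                          msv_y=msv_y, snapshot_times=snap_t, snapshots=snaps,
                          final=final, params=params,
                          time_unit=str(f.attrs.get("time_unit", "tau_r")))


def save_field(path: str | Path, field: DirectorField) -> None:
    """Plain binary dump (no metadata) of a single director field."""
    np.save(path, field.theta)


def load_field(path: str | Path, time: float = 0.0) -> DirectorField:
    return DirectorField(np.load(path), time)


def msv_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame({"time": traj.times, "msv": traj.msv,
                         "msv_x": traj.msv_x, "msv_y": traj.msv_y})


def write_msv_csv(path: str | Path, traj: Trajectory) -> None:
    msv_frame(traj).to_csv(path, index=False)


def write_kymograph_csv(path: str | Path, kymo) -> None:
    """Kymograph as a CSV matrix: first column time, remaining columns the
    enstrophy at each x position."""
    df = pd.DataFrame(kymo.eps, columns=[f"x={x:.6f}" for x in kymo.x])
    df.insert(0, "time", kymo.times)
    df.to_csv(path, index=False)
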