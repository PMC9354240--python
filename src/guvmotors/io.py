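"""Trajectory-table CSV, TIFF stack and YAML config I/O."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import FrameStack
from .params import (
    AcquisitionParams,
    CompartmentParams,
    ExperimentCondition,
    MotorParams,
    Trajectory,
)

TRAJ_COLUMNS = ["condition_id", "guv_id", "particle_id", "frame", "time_s",
                "x_um", "y_um"]


def trajectories_to_frame(trajs: list[Trajectory], condition_id: str = "",
                          guv_id: int = 0) -> pd.DataFrame:
    rows = []
    for t in trajs:
        for f, (time, (x, y)) in enumerate(zip(t.times, t.xy)):
            rows.append((condition_id, guv_id, t.particle_id, f, time, x, y))
    return pd.DataFrame(rows, columns=TRAJ_COLUMNS)


def write_trajectories(path, trajs: list[Trajectory], condition_id: str = "",
                       guv_id: int = 0) -> None:
    trajectories_to_frame(trajs, condition_id, guv_id).to_csv(path, index=False)


def read_trajectories(path) -> dict[tuple[str, int, int], Trajectory]:
    """Read the standard trajectory table; keys (condition_id, guv_id,
    particle_id)."""
    df = pd.read_csv(path, keep_default_na=False)
    out = {}
    for (cond, guv, pid), grp in df.groupby(
            ["condition_id", "guv_id", "particle_id"], sort=True):
        grp = grp.sort_values("frame")
        out[(str(cond), int(guv), int(pid))] = Trajectory(
            particle_id=int(pid), times=grp["time_s"].to_numpy(),
            xy=grp[["x_um", "y_um"]].to_numpy())
    return out


def write_stack(path, stack: FrameStack) -> None:
    """Multi-page TIFF (plane order = z order) with a YAML metadata
    sidecar holding pixel size and z spacing."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels.astype(np.float32))
    meta = {"pixel_size_um": float(stack.pixel_size),
            "z_spacing_um": float(stack.z_spacing),
            "n_planes": int(stack.n_planes)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_stack(path) -> FrameStack:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(".yaml")
    pixel_size, z_spacing = 1.0, 0.0
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        z_spacing = float(meta.get("z_spacing_um", 0.0))
    return FrameStack(pixels=np.asarray(pixels, dtype=float),
                      pixel_size=pixel_size, z_spacing=z_spacing)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def condition_from_dict(d: dict, default_seed: int = 0) -> ExperimentCondition:
    motor = MotorParams(**d.get("motor", {}))
    return ExperimentCondition(
        label=d["label"], fuel=float(d.get("fuel", 0.0)),
        guv_diameter=d.get("guv_diameter", "bulk"),
        n_particles=int(d.get("n_particles", 40)),
        crowding_beta=float(d.get("crowding_beta", 0.0)),
        membrane=d.get("membrane", "bilayer"),
        seed=int(d.get("seed", default_seed)), motor=motor)


def acquisition_from_dict(d: dict | None) -> AcquisitionParams:
    return AcquisitionParams(**(d or {}))
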