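"""Trajectory and metrics file formats.

Trajectories travel as tidy CSV (comma-separated, header row, UTF-8,
'.' decimal): columns ``time_s, rep, fish_id, x_cm, y_cm, heading_rad``.
Bout logs: ``onset_s, rep, fish_id, turn_rad, displacement_cm``.  A short
``# key=value`` comment header carries the metadata (units: cm, seconds,
radians in trajectory files) needed to rebuild TrajectorySet objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TrajectorySet

_META_KEYS = ("dt", "age", "variant", "arena_diameter", "body_length", "body_height")


def _meta_header(traj: TrajectorySet) -> str:
    parts = [f"{k}={getattr(traj, k)}" for k in _META_KEYS]
    return "# shoalsim trajectory; units: cm, s, rad; " + "; ".join(parts) + "\n"


def write_trajectories(runs, path) -> None:
    """Write one or more runs (repetitions) to a trajectory CSV."""
    runs = runs if isinstance(runs, (list, tuple)) else [runs]
    path = Path(path)
    frames = [r.to_frame(rep=k) for k, r in enumerate(runs)]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_header(runs[0]))
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False)


def write_bouts(runs, path) -> None:
    runs = runs if isinstance(runs, (list, tuple)) else [runs]
    frames = []
    for k, r in enumerate(runs):
        df = r.bouts.copy()
        df.insert(1, "rep", k)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_trajectories(path):
    """Read a trajectory CSV back into a list of TrajectorySet (one per rep)."""
    path = Path(path)
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for part in first.split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k.strip()] = v.strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    runs = []
    for rep, sub in df.groupby("rep", sort=True):
        piv_t = np.sort(sub["time_s"].unique())
        fish = np.sort(sub["fish_id"].unique())
        T, N = len(piv_t), len(fish)
        sub = sub.sort_values(["time_s", "fish_id"])
        positions = sub[["x_cm", "y_cm"]].to_numpy().reshape(T, N, 2)
        headings = sub["heading_rad"].to_numpy().reshape(T, N)
        dt = float(meta.get("dt", np.median(np.diff(piv_t)) if T > 1 else 0.02))
        runs.append(
            TrajectorySet(
                time=piv_t,
                positions=positions,
                headings=headings,
                bouts=pd.DataFrame(
                    columns=["onset_s", "fish_id", "turn_rad", "displacement_cm"]
                ),
                dt=dt,
                age=int(float(meta.get("age", 7))),
                variant=meta.get("variant", "unknown"),
                arena_diameter=float(meta.get("arena_diameter", 6.5)),
                body_length=float(meta.get("body_length", 0.4)),
                body_height=float(meta.get("body_height", 0.2)),
            )
        )
    return runs


def write_summary(summary: dict, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
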