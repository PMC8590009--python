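"""Deterministic hand-constructed fixtures with known statistics.

Small synthetic trajectory tables whose group statistics are known in
closed form; the test suite uses them as oracles and the ``make_fixtures``
entry point writes them to CSV for inspection.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd


def collinear_group(n_frames: int = 10, dt: float = 0.02) -> pd.DataFrame:
    """Three stationary fish at x = 0, 1, 5: mean NN1 = (1 + 1 + 4) / 3 = 2."""
    xs = [0.0, 1.0, 5.0]
    rows = []
    for t in range(n_frames):
        for i, x in enumerate(xs):
            rows.append(
                {"time_s": t * dt, "rep": 0, "fish_id": i, "x_cm": x, "y_cm": 0.0,
                 "heading_rad": 0.0}
            )
    return pd.DataFrame(rows)


def aligned_group(n_fish: int = 5, n_frames: int = 10, dt: float = 0.02) -> pd.DataFrame:
    """Fish marching east in lockstep: alignment exactly 1."""
    rows = []
    for t in range(n_frames):
        for i in range(n_fish):
            rows.append(
                {
                    "time_s": t * dt,
                    "rep": 0,
                    "fish_id": i,
                    "x_cm": 0.1 * t,
                    "y_cm": float(i),
                    "heading_rad": 0.0,
                }
            )
    return pd.DataFrame(rows)


def two_bump_speed(dt: float = 0.02):
    """A speed trace with two bumps separated by constructed strict minima.

    Returns ``(speed, expected_bouts)`` where ``expected_bouts`` lists the
    (start, end) indices of the inter-minimum segments, one per bump.
    """
    speed = np.array(
        [1.0, 0.1, 0.5, 1.0, 0.5, 0.1, 0.5, 1.0, 0.5, 0.1, 1.0], dtype=float
    )
    expected = [(1, 5), (5, 9)]
    return speed, expected


def make_fixtures(seed: int = 0, outdir=None) -> dict:
    """Build the fixture bundle, optionally writing CSVs to ``outdir``."""
    rng = np.random.default_rng(seed)
    bundle = {
        "collinear_group": collinear_group(),
        "aligned_group": aligned_group(),
    }
    speed, expected = two_bump_speed()
    bundle["two_bump_speed"] = pd.DataFrame(
        {"frame": np.arange(len(speed)), "speed_cm_s": speed}
    )
    bundle["two_bump_expected"] = pd.DataFrame(
        expected, columns=["start", "end"]
    )
    # a jittered copy exercises robustness without changing bout structure
    jitter = speed + 0.0 * rng.standard_normal(len(speed))
    bundle["two_bump_speed"]["speed_jittered"] = jitter
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
    return bundle
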