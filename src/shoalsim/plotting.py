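"""Matplotlib helpers for response curves and group trajectories."""

from __future__ import annotations

import numpy as np


def plot_response_curves(curves, v_max: float = 90.0, ax=None):
    """Overlay turn-probability curves (left-stimulus frame) for several ages."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = np.linspace(0.0, v_max, 400)
    for curve in curves:
        ax.plot(v, curve(v), label=f"{curve.age} dpf")
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("vertical occupancy (deg)")
    ax.set_ylabel("P(turn right | stimulus on left eye)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_trajectories(traj, ax=None, max_points: int = 5000):
    """Plot a group's paths inside the arena outline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    stride = max(1, traj.positions.shape[0] // max_points)
    pos = traj.positions[::stride]
    for i in range(traj.n_agents):
        ax.plot(pos[:, i, 0], pos[:, i, 1], lw=0.6)
    theta = np.linspace(0, 2 * np.pi, 200)
    r = traj.arena_diameter / 2.0
    ax.plot(r * np.cos(theta), r * np.sin(theta), color="k", lw=1.0)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_title(f"{traj.age} dpf, {traj.variant}")
    return ax
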