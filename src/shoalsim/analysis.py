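"""Individual and group statistics of swimming trajectories.

Implements the standard measurements for bout-swimming groups: central-
difference kinematics, speed-minimum bout segmentation, normalized group
dispersion against a shuffled-identity nearest-neighbor baseline, heading
alignment (polarization), and binned inference of turning responses with
binomial confidence intervals.

Dispersion is ``log(NN1 / NN1_shuffled)`` with the natural logarithm by
default: the mean nearest-neighbor distance of the real group over the mean
of pseudo-groups assembled by drawing each member from a different
repetition.  Zero means indistinguishable from non-interacting fish,
positive means overdispersed, negative aggregated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.stats.proportion import proportion_confint

from .geometry import eye_extents_timeseries

_LOG_BASE = {"e": 1.0, "2": math.log(2.0), "10": math.log(10.0)}


# ---------------------------------------------------------------------------
# kinematics


@dataclass
class KinematicsSeries:
    """Central-difference kinematics of a group.

    Endpoints of the input are dropped.  ``direction`` is the unit heading of
    motion, NaN where the instantaneous speed is zero (flagged in ``moving``).
    """

    time: np.ndarray
    velocity: np.ndarray  # (T-2, N, 2) cm/s
    speed: np.ndarray     # (T-2, N)
    direction: np.ndarray  # (T-2, N, 2), NaN when not moving
    moving: np.ndarray    # (T-2, N) bool
    dt: float


def compute_kinematics(positions, time=None, dt: float | None = None) -> KinematicsSeries:
    """Symmetric-difference velocity, speed and motion direction.

    ``positions`` is (T, N, 2) or (T, 2); velocity at frame ``t`` is
    ``(x(t+dt) - x(t-dt)) / 2dt``.  The time base must be uniform.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    if pos.shape[0] < 3:
        raise ValueError("need at least 3 samples for central differences")
    if time is not None:
        time = np.asarray(time, dtype=float)
        steps = np.diff(time)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time base must be uniform")
        dt = float(steps[0])
    if dt is None:
        raise ValueError("provide either a time vector or dt")
    vel = (pos[2:] - pos[:-2]) / (2.0 * dt)
    speed = np.hypot(vel[..., 0], vel[..., 1])
    moving = speed > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = vel / speed[..., None]
    direction[~moving] = np.nan
    t = (
        time[1:-1]
        if time is not None
        else np.arange(1, pos.shape[0] - 1) * dt
    )
    return KinematicsSeries(
        time=t, velocity=vel, speed=speed, direction=direction, moving=moving, dt=dt
    )


# ---------------------------------------------------------------------------
# bout segmentation


def segment_bouts(
    speed,
    dt: float,
    headings=None,
    positions=None,
    smooth_window: int = 0,
    speed_eps: float = 1e-9,
) -> pd.DataFrame:
    """Segment a single fish's speed trace into bouts.

    A bout is the motion between two consecutive interior local minima of
    the speed profile (flat minima count once, at their midpoint).  Columns:
    ``start, end`` (frame indices of the delimiting minima), ``onset_s``
    (first frame inside the segment where the speed exceeds ``speed_eps`` --
    the moment motion actually starts), ``duration_s``, ``path_length_cm``
    (if positions given) and ``turn_rad`` (heading change start-to-end,
    positive rightward, if headings given).

    Segments whose peak speed never exceeds ``speed_eps`` are discarded
    (no motion, hence no bout); a flat trace yields no bouts.
    """
    s = np.asarray(speed, dtype=float)
    if s.ndim != 1:
        raise ValueError("segment_bouts expects a 1-D speed series")
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        s = np.convolve(s, kernel, mode="same")
    minima, _ = find_peaks(-s)
    rows = []
    for a, b in zip(minima[:-1], minima[1:]):
        seg = s[a : b + 1]
        if seg.max() <= speed_eps:
            continue
        above = np.flatnonzero(seg > speed_eps)
        onset = a + int(above[0])
        row = {
            "start": int(a),
            "end": int(b),
            "onset_s": onset * dt,
            "duration_s": (b - a) * dt,
        }
        if positions is not None:
            p = np.asarray(positions, dtype=float)[a : b + 1]
            row["path_length_cm"] = float(
                np.hypot(*np.diff(p, axis=0).T).sum()
            )
        if headings is not None:
            h = np.asarray(headings, dtype=float)
            dh = (h[b] - h[a] + math.pi) % (2.0 * math.pi) - math.pi
            row["turn_rad"] = -dh  # rightward (clockwise) positive
        rows.append(row)
    cols = ["start", "end", "onset_s", "duration_s"]
    if positions is not None:
        cols.append("path_length_cm")
    if headings is not None:
        cols.append("turn_rad")
    return pd.DataFrame(rows, columns=cols)


def segment_trajectory_bouts(traj) -> pd.DataFrame:
    """Segment every fish of a :class:`~shoalsim.simulate.TrajectorySet`."""
    kin = compute_kinematics(traj.positions, time=traj.time)
    frames = []
    for i in range(traj.n_agents):
        df = segment_bouts(
            kin.speed[:, i],
            dt=traj.dt,
            headings=traj.headings[1:-1, i],
            positions=traj.positions[1:-1, i],
        )
        df.insert(0, "fish_id", i)
        # indices refer to the trimmed kinematics frame; shift to trajectory
        df["start"] += 1
        df["end"] += 1
        df["onset_s"] += traj.dt
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# group statistics


def nn1(positions) -> np.ndarray:
    """Mean nearest-neighbor distance per time point.

    ``positions`` is (..., N, 2); returns an array of shape ``(...)``.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[-2] < 2:
        raise ValueError("nearest-neighbor distance needs at least 2 fish")
    diff = pos[..., :, None, :] - pos[..., None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    n = pos.shape[-2]
    d[..., np.arange(n), np.arange(n)] = np.inf
    return d.min(axis=-1).mean(axis=-1)


def dispersion(positions, baseline: float, log_base: str = "e"):
    """Normalized dispersion ``log(NN1(t) / baseline)``.

    Coincident fish (NN1 = 0) yield ``-inf``, which propagates as a flag
    rather than raising.
    """
    if baseline <= 0:
        raise ValueError("shuffled NN1 baseline must be positive")
    ratio = nn1(positions) / baseline
    with np.errstate(divide="ignore"):
        return np.log(ratio) / _LOG_BASE[log_base]


def group_dispersion(positions, baseline: float, log_base: str = "e") -> float:
    """Per-group scalar dispersion: ``log(<NN1>_t / baseline)``.

    The time average enters the logarithm so that a non-interacting group --
    whose NN1 distribution matches the shuffled pseudo-groups exactly --
    scores zero in expectation.  Averaging ``log(NN1(t)/baseline)`` over
    time instead would carry a negative Jensen offset of order
    ``-Var[NN1]/2<NN1>^2`` even at chance.
    """
    if baseline <= 0:
        raise ValueError("shuffled NN1 baseline must be positive")
    return float(math.log(float(np.mean(nn1(positions))) / baseline)
                 / _LOG_BASE[log_base])


def shuffled_nn1(
    pool: Sequence,
    n_assemblies: int = 1000,
    stride: int = 1,
    seed=None,
    time_resolved: bool = False,
):
    """Nearest-neighbor baseline from shuffled pseudo-groups.

    ``pool`` is a list of position arrays (T, N, 2) (or TrajectorySets),
    each an independent group of the same size.  Every pseudo-group shuffles
    fish identities across groups: identity ``i`` is taken from a distinct
    source group for every ``i`` (a random group subset and a random identity
    permutation), at matched time points.  Returns the mean NN1 over
    ``n_assemblies`` pseudo-groups (a scalar, or a per-time-point array if
    ``time_resolved``).
    """
    arrs = [getattr(p, "positions", p) for p in pool]
    arrs = [np.asarray(a, dtype=float) for a in arrs]
    n_groups = len(arrs)
    n_fish = arrs[0].shape[1]
    if n_groups < n_fish:
        raise ValueError(
            f"need at least {n_fish} source groups to assemble pseudo-groups "
            f"of {n_fish} fish, got {n_groups}"
        )
    t_min = min(a.shape[0] for a in arrs)
    stacked = np.stack([a[:t_min:stride] for a in arrs])  # (G, T', N, 2)
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_assemblies):
        gsel = rng.choice(n_groups, size=n_fish, replace=False)
        fsel = rng.permutation(n_fish)
        pseudo = stacked[gsel, :, fsel, :]  # (N, T', 2)
        vals = nn1(np.moveaxis(pseudo, 0, 1))
        acc = vals if acc is None else acc + vals
    mean_t = acc / n_assemblies
    return mean_t if time_resolved else float(mean_t.mean())


def alignment(directions) -> np.ndarray:
    """Polarization: modulus of the mean unit direction vector, in [0, 1].

    ``directions`` is (..., N, 2) unit vectors; fish with NaN direction
    (not moving) are excluded from the mean, and a time point with no valid
    fish comes back NaN.
    """
    d = np.asarray(directions, dtype=float)
    valid = ~np.isnan(d[..., 0])
    n_valid = valid.sum(axis=-1)
    dd = np.where(valid[..., None], d, 0.0)
    mean_vec = dd.sum(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.hypot(mean_vec[..., 0], mean_vec[..., 1]) / n_valid
    return np.where(n_valid > 0, out, np.nan)


def alignment_from_headings(headings) -> np.ndarray:
    """Polarization computed from heading angles (radians), shape (..., N)."""
    h = np.asarray(headings, dtype=float)
    return alignment(np.stack([np.cos(h), np.sin(h)], axis=-1))


# ---------------------------------------------------------------------------
# binned turn-response inference


@dataclass
class BinnedTurnResponse:
    """Binned estimates of a turning (or bout-rate) probability.

    ``table`` columns: bin_left, bin_right, bin_center, n_success, n_total,
    p, ci_low, ci_high, empty.  For ``kind='bout_rate'`` an extra
    ``rate_hz`` column divides the per-bin probability by the sampling
    interval.
    """

    table: pd.DataFrame
    covariate: str
    bin_width: float
    kind: str = "turn"

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table[~self.table["empty"]]
        ycol = "rate_hz" if self.kind == "bout_rate" else "p"
        yerr = None
        if self.kind == "turn":
            yerr = np.vstack(
                [t["p"] - t["ci_low"], t["ci_high"] - t["p"]]
            )
        ax.errorbar(t["bin_center"], t[ycol], yerr=yerr, fmt="o-", **kwargs)
        if self.kind == "turn":
            ax.axhline(0.5, color="gray", lw=0.8, ls="--")
        ax.set_xlabel(self.covariate)
        ax.set_ylabel("bout rate (Hz)" if self.kind == "bout_rate" else "P(turn right)")
        return ax


def _ci(successes, totals, method: str):
    meth = {"clopper-pearson": "beta", "normal": "normal", "wilson": "wilson"}[method]
    lo = np.empty(len(totals))
    hi = np.empty(len(totals))
    for i, (s, n) in enumerate(zip(successes, totals)):
        if n == 0:
            lo[i] = hi[i] = np.nan
        else:
            lo[i], hi[i] = proportion_confint(s, n, alpha=0.05, method=meth)
    return lo, hi


def binned_binomial(
    values, successes, bin_width, covariate="x", ci_method="clopper-pearson",
    kind="turn", dt=None,
) -> BinnedTurnResponse:
    """Bin a binary outcome against a covariate with binomial 95% CIs."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(successes, dtype=bool)
    if x.size == 0:
        raise ValueError("no events to bin")
    lo_edge = math.floor(x.min() / bin_width) * bin_width
    hi_edge = math.ceil(x.max() / bin_width) * bin_width
    if hi_edge <= lo_edge:
        hi_edge = lo_edge + bin_width
    edges = np.arange(lo_edge, hi_edge + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    n_total = np.bincount(idx, minlength=len(edges) - 1)
    n_succ = np.bincount(idx, weights=y.astype(float), minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        p = n_succ / n_total
    ci_lo, ci_hi = _ci(n_succ.astype(int), n_total, ci_method)
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "bin_center": (edges[:-1] + edges[1:]) / 2.0,
            "n_success": n_succ.astype(int),
            "n_total": n_total.astype(int),
            "p": p,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
            "empty": n_total == 0,
        }
    )
    out = BinnedTurnResponse(
        table=table, covariate=covariate, bin_width=float(bin_width), kind=kind
    )
    if kind == "bout_rate":
        if dt is None:
            raise ValueError("bout-rate binning needs the sampling interval dt")
        out.table["rate_hz"] = out.table["p"] / dt
    return out


def infer_turn_response(
    trajs,
    covariate: str = "delta_occupancy",
    bin_width: float | None = None,
    wall_exclusion_bl: float = 3.0,
    ci_method: str = "clopper-pearson",
    bouts=None,
    span_deg: float = 165.0,
) -> BinnedTurnResponse:
    """Infer a binned turn-response curve from trajectories.

    ``covariate`` is one of:

    * ``'delta_occupancy'`` -- inter-eye difference of total horizontal
      occupancy at each bout onset (deg; negative = more on the left);
      success = rightward turn.  Events within ``wall_exclusion_bl`` body
      lengths of the wall are discarded.
    * ``'wall_distance'`` -- distance to the wall in body lengths; success =
      turn away from the nearest wall.  Default bin width 1 BL.
    * ``'sigma_occupancy'`` -- summed occupancy over both eyes, evaluated at
      every decision opportunity (time step outside a bout); success = bout
      initiated.  The result carries a per-bin bout rate (probability / dt).

    ``trajs`` is a TrajectorySet or list of them; ``bouts`` optionally
    overrides each trajectory's own bout log with segmented bouts (a list of
    DataFrames with ``onset_s, fish_id, turn_rad``).
    """
    if covariate not in ("delta_occupancy", "wall_distance", "sigma_occupancy"):
        raise ValueError(f"unknown covariate {covariate!r}")
    if bin_width is None:
        bin_width = 1.0 if covariate == "wall_distance" else 5.0
    traj_list = trajs if isinstance(trajs, (list, tuple)) else [trajs]
    if bouts is not None and not isinstance(bouts, (list, tuple)):
        bouts = [bouts]

    values: list = []
    successes: list = []
    dt = traj_list[0].dt
    for k, traj in enumerate(traj_list):
        radius = traj.arena_diameter / 2.0
        bl = traj.body_length
        log = bouts[k] if bouts is not None else traj.bouts
        onset_idx = np.clip(
            np.round(np.asarray(log["onset_s"]) / traj.dt).astype(int),
            0,
            len(traj.time) - 1,
        )
        fish = np.asarray(log["fish_id"], dtype=int)
        turn_right = np.asarray(log["turn_rad"], dtype=float) > 0

        pos_at = traj.positions[onset_idx, fish]  # (E, 2)
        r_at = np.hypot(pos_at[:, 0], pos_at[:, 1])
        wall_dist_bl = (radius - r_at) / bl

        if covariate == "wall_distance":
            # success = turn away from the nearest wall: the wall is on the
            # right when the outward radial lies right of the heading
            hdg = traj.headings[onset_idx, fish]
            outward = np.arctan2(pos_at[:, 1], pos_at[:, 0])
            rel = (outward - hdg + math.pi) % (2 * math.pi) - math.pi
            wall_on_right = rel <= 0
            away = np.where(wall_on_right, ~turn_right, turn_right)
            values.append(wall_dist_bl)
            successes.append(away)
            continue

        left_tot, right_tot = eye_extents_timeseries(
            traj.positions, traj.headings, bl, span_deg=span_deg
        )
        if covariate == "delta_occupancy":
            keep = wall_dist_bl >= wall_exclusion_bl
            delta = (right_tot - left_tot)[onset_idx, fish]
            values.append(delta[keep])
            successes.append(turn_right[keep])
        else:  # sigma_occupancy
            T, N = left_tot.shape
            sigma = left_tot + right_tot
            in_bout = np.zeros((T, N), dtype=bool)
            steps = max(1, int(round(0.32 / traj.dt)))
            for t0, i in zip(onset_idx, fish):
                in_bout[t0 + 1 : t0 + steps, i] = True
            onset_mask = np.zeros((T, N), dtype=bool)
            onset_mask[onset_idx, fish] = True
            r_all = np.hypot(traj.positions[..., 0], traj.positions[..., 1])
            ok = (~in_bout) & ((radius - r_all) / bl >= wall_exclusion_bl)
            values.append(sigma[ok])
            successes.append(onset_mask[ok])

    x = np.concatenate(values)
    y = np.concatenate(successes)
    kind = "bout_rate" if covariate == "sigma_occupancy" else "turn"
    return binned_binomial(
        x, y, bin_width, covariate=covariate, ci_method=ci_method, kind=kind,
        dt=dt if kind == "bout_rate" else None,
    )
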