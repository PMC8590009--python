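"""Bout-based agent simulation of groups of larval zebrafish.

Agents swim in a circular arena in discrete bouts.  While stationary, each
agent initiates a bout with a fixed per-step hazard chosen so that the
realized bout rate matches the configured age-specific rate despite the
320 ms refractory period of an executing bout.  At bout onset the agent
picks a turn direction:

* within two body lengths of the wall it turns away from the wall with the
  wall-response probability and ignores its neighbors entirely;
* otherwise the turn direction is a Bernoulli draw from the social decision
  rule of the model variant -- the per-fish vertical-occupancy pipeline
  (``vr_social``), the inter-eye occupancy-difference curve
  (``group_derived``), or a fair coin (``nonsocial``).

Turn magnitude is drawn from a half-normal distribution independent of the
direction: the social signal modulates only the probability of a directed
turn, never its size.  The bout then displaces the agent by the age's bout
size along the new heading over 16 time steps with a triangular speed
profile, truncated at the arena boundary.

Sign conventions: headings are radians, counter-clockwise positive, in a
frame with x east and y north.  Logged turn angles are positive for
rightward (clockwise) turns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig, default_config
from .responses import GroupDeltaCurve, ResponseCurve, WallResponse

VARIANTS = ("nonsocial", "vr_social", "group_derived")

_DEG = 180.0 / math.pi


@dataclass
class AgentState:
    """One simulated fish at one instant."""

    position: np.ndarray
    heading: float
    body_length: float
    body_height: float
    bout_steps_left: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def stationary(self) -> bool:
        return self.bout_steps_left == 0


@dataclass(frozen=True)
class SimulationConfig:
    """Fully resolved parameters for one simulation run."""

    age: int
    variant: str
    arena_diameter: float
    dt: float
    duration: float
    n_agents: int
    bout_rate: float
    bout_size: float
    bout_duration: float
    body_length: float
    body_height: float
    start_fraction: float
    turn_sigma_deg: float
    speed_profile: str
    span_deg: float
    curve: ResponseCurve
    group_curve: GroupDeltaCurve
    wall: WallResponse

    @classmethod
    def from_run_config(
        cls, cfg: RunConfig | None = None, age: int = 7,
        variant: str = "vr_social", **overrides,
    ) -> "SimulationConfig":
        cfg = cfg or default_config()
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
        ap = cfg.age_params(age)
        sim = cfg.simulation
        out = cls(
            age=int(age),
            variant=variant,
            arena_diameter=ap.arena_diameter_cm,
            dt=sim.dt_s,
            duration=sim.duration_s,
            n_agents=sim.n_agents,
            bout_rate=ap.bout_rate_hz,
            bout_size=ap.bout_size_cm,
            bout_duration=sim.bout_duration_s,
            body_length=ap.fish_length_cm,
            body_height=ap.fish_height_cm,
            start_fraction=sim.start_fraction,
            turn_sigma_deg=sim.turn_sigma_deg,
            speed_profile=sim.speed_profile,
            span_deg=cfg.retina.ray_span_deg,
            curve=cfg.response_curve(age),
            group_curve=cfg.group_delta_curve(age),
            wall=cfg.wall_response(),
        )
        return replace(out, **overrides) if overrides else out

    def validate(self) -> None:
        for name in (
            "arena_diameter", "dt", "duration", "bout_rate", "bout_size",
            "bout_duration", "body_length", "body_height", "turn_sigma_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        if self.n_agents < 1:
            raise ValueError("SimulationConfig.n_agents must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 < self.start_fraction <= 1:
            raise ValueError("SimulationConfig.start_fraction must lie in (0, 1]")
        if 1.0 / self.bout_rate <= self.bout_duration:
            raise ValueError(
                "bout_rate too high: mean inter-bout interval must exceed "
                "the bout duration"
            )
        if self.speed_profile not in ("triangular", "instant"):
            raise ValueError("speed_profile must be 'triangular' or 'instant'")

    @property
    def initiation_hazard(self) -> float:
        """Per-step probability of starting a bout while stationary.

        Compensated for the refractory bout duration so the realized bout
        rate equals ``bout_rate``: the onset-to-onset cycle is the bout
        duration (whose first step doubles as the successful decision step)
        plus a geometric wait of ``1/hazard - 1`` further steps.
        """
        wait = 1.0 / self.bout_rate - self.bout_duration + self.dt
        return self.dt / wait

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def bout_steps(self) -> int:
        return max(1, int(round(self.bout_duration / self.dt)))


@dataclass
class TrajectorySet:
    """Output of one simulation run: a uniformly sampled group trajectory.

    ``positions`` has shape (T, N, 2) in cm, ``headings`` (T, N) in radians;
    ``bouts`` is the event log with columns ``onset_s, fish_id, turn_rad,
    displacement_cm`` (turn positive rightward).
    """

    time: np.ndarray
    positions: np.ndarray
    headings: np.ndarray
    bouts: pd.DataFrame
    dt: float
    age: int
    variant: str
    arena_diameter: float
    body_length: float
    body_height: float
    seed: int | None = None

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def to_frame(self, rep: int = 0) -> pd.DataFrame:
        """Tidy table: time_s, rep, fish_id, x_cm, y_cm, heading_rad."""
        T, N, _ = self.positions.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.time, N),
                "rep": rep,
                "fish_id": np.tile(np.arange(N), T),
                "x_cm": self.positions[:, :, 0].ravel(),
                "y_cm": self.positions[:, :, 1].ravel(),
                "heading_rad": self.headings.ravel(),
            }
        )


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _eye_overlap_deg(lo: float, hi: float, span: float):
    """Scalar twin of geometry._interval_eye_overlap returning lengths only."""
    left = right = 0.0
    for shift in (-360.0, 0.0, 360.0):
        a, b = lo + shift, hi + shift
        left += max(0.0, min(b, span) - max(a, 0.0))
        right += max(0.0, min(b, 0.0) - max(a, -span))
    return left, right


def social_turn_probability(
    focal: AgentState, others: Sequence[AgentState], config: SimulationConfig
) -> float:
    """Deterministic p(turn right) for a mid-arena agent under the variant's
    social rule (the wall rule is handled by :func:`decide_turn`)."""
    if config.variant == "nonsocial" or not others:
        return 0.5
    fx, fy = focal.position
    hdg_deg = focal.heading * _DEG
    span = config.span_deg
    if config.variant == "vr_social":
        left_vb: list = []   # (v, bias) on the left eye
        right_vb: list = []
        for nb in others:
            dx, dy = nb.position[0] - fx, nb.position[1] - fy
            d = math.hypot(dx, dy)
            if d == 0:
                continue
            bearing = math.atan2(dy, dx) * _DEG - hdg_deg
            bearing = (bearing + 180.0) % 360.0 - 180.0
            if abs(bearing) > span:
                continue  # blind zone
            v = 2.0 * math.atan(nb.body_height / d) * _DEG
            b = config.curve.probability(v) - 0.5
            if bearing > 0:
                left_vb.append((v, b))
            else:
                right_vb.append((v, -b))
        s = 0.5
        for vb in (left_vb, right_vb):
            if not vb:
                continue
            if config.age == 7:
                tot = sum(v for v, _ in vb)
                if tot > 0:
                    s += sum(v * b for v, b in vb) / tot
            else:
                s += sum(b for _, b in vb) / len(vb)
        return min(1.0, max(0.0, s))
    # group_derived: inter-eye difference of summed head-to-tail extents
    tot_left = tot_right = 0.0
    for nb in others:
        half = 0.5 * nb.body_length
        ux, uy = math.cos(nb.heading), math.sin(nb.heading)
        b1 = b2 = None
        for sx in (half, -half):
            px, py = nb.position[0] + sx * ux - fx, nb.position[1] + sx * uy - fy
            if px == 0 and py == 0:
                b1 = None
                break
            ang = math.atan2(py, px) * _DEG - hdg_deg
            ang = (ang + 180.0) % 360.0 - 180.0
            if b1 is None:
                b1 = ang
            else:
                b2 = ang
        if b1 is None or b2 is None:
            continue
        rel = (b2 - b1 + 180.0) % 360.0 - 180.0
        lo, hi = b1 + min(rel, 0.0), b1 + max(rel, 0.0)
        l, r = _eye_overlap_deg(lo, hi, span)
        tot_left += l
        tot_right += r
    return float(config.group_curve(tot_right - tot_left))


def decide_turn(
    focal: AgentState,
    others: Sequence[AgentState],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    """Signed turn angle (radians, positive = rightward) for a bout onset.

    Draw order is fixed (direction, then magnitude) so that model variants
    with identical probabilities produce identical trajectories under the
    same seed.
    """
    x, y = focal.position
    r = math.hypot(x, y)
    radius = config.arena_diameter / 2.0
    dist_bl = (radius - r) / config.body_length
    if dist_bl < config.wall.engage_distance_bl and r > 0:
        # wall rule: neighbors are ignored
        p_away = config.wall(max(dist_bl, 0.0))
        inward = math.atan2(-y, -x)
        delta = _wrap_pi(inward - focal.heading)
        # a rightward (clockwise) turn decreases the heading angle
        away_is_right = delta <= 0
        p_right = p_away if away_is_right else 1.0 - p_away
    else:
        p_right = social_turn_probability(focal, others, config)
    rightward = rng.random() < p_right
    magnitude = abs(rng.normal(0.0, config.turn_sigma_deg)) / _DEG
    return magnitude if rightward else -magnitude


def _bout_profile(config: SimulationConfig) -> np.ndarray:
    """Per-step displacement fractions of a bout (sums to 1)."""
    k = config.bout_steps
    if config.speed_profile == "instant":
        w = np.zeros(k)
        w[0] = 1.0
        return w
    # triangular speed profile peaking mid-bout, zero at the endpoints
    t = np.arange(k) + 0.5
    w = np.minimum(t, k - t)
    return w / w.sum()


def execute_bout(
    agent: AgentState, turn: float, config: SimulationConfig
) -> tuple[AgentState, np.ndarray]:
    """Apply one full bout to an agent, returning the new state and the
    per-step path samples (shape (bout_steps, 2)).

    The heading rotates by ``turn`` (positive rightward) at onset; the agent
    then travels ``bout_size`` cm along the new heading, truncated at the
    arena wall (position clipped to the boundary, heading unchanged).
    """
    radius = config.arena_diameter / 2.0
    heading = _wrap_pi(agent.heading - turn)
    ux, uy = math.cos(heading), math.sin(heading)
    fractions = _bout_profile(config) * config.bout_size
    x, y = agent.position
    path = np.empty((len(fractions), 2))
    for i, step in enumerate(fractions):
        x, y, _ = _advance(x, y, ux, uy, step, radius)
        path[i] = (x, y)
    new = AgentState(
        position=np.array([x, y]),
        heading=heading,
        body_length=agent.body_length,
        body_height=agent.body_height,
        bout_steps_left=0,
    )
    return new, path


def _advance(x, y, ux, uy, step, radius):
    """One within-bout displacement step with wall truncation."""
    nx, ny = x + step * ux, y + step * uy
    if nx * nx + ny * ny <= radius * radius:
        return nx, ny, False
    # clip along the motion direction to the boundary circle
    b = x * ux + y * uy
    c = x * x + y * y - radius * radius
    t = -b + math.sqrt(max(b * b - c, 0.0))
    t = min(max(t, 0.0), step)
    return x + t * ux, y + t * uy, True


def run_simulation(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = 0,
    initial_positions=None,
    initial_headings=None,
) -> TrajectorySet:
    """Run one simulation; deterministic given the seed.

    Agents start at uniform random positions within ``start_fraction`` of
    the arena diameter with uniform random headings (overridable for
    controlled experiments).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_agents
    n_steps = config.n_steps
    radius = config.arena_diameter / 2.0
    start_radius = config.start_fraction * radius
    bout_steps = config.bout_steps
    hazard = config.initiation_hazard
    profile = _bout_profile(config) * config.bout_size
    sigma_rad = config.turn_sigma_deg / _DEG
    wall_engage = config.wall.engage_distance_bl * config.body_length

    # initial conditions (always drawn, so overrides keep the draw order)
    r0 = start_radius * np.sqrt(rng.random(n))
    phi0 = rng.random(n) * 2.0 * math.pi
    x = r0 * np.cos(phi0)
    y = r0 * np.sin(phi0)
    hdg = rng.random(n) * 2.0 * math.pi - math.pi
    if initial_positions is not None:
        pos0 = np.asarray(initial_positions, dtype=float)
        x, y = pos0[:, 0].copy(), pos0[:, 1].copy()
    if initial_headings is not None:
        hdg = np.asarray(initial_headings, dtype=float).copy()

    T = n_steps + 1
    positions = np.empty((T, n, 2))
    headings = np.empty((T, n))
    positions[0, :, 0] = x
    positions[0, :, 1] = y
    headings[0] = hdg

    xs = list(map(float, x))
    ys = list(map(float, y))
    hs = list(map(float, hdg))
    uxs = [math.cos(h) for h in hs]
    uys = [math.sin(h) for h in hs]
    remaining = [0] * n

    bout_onsets: list = []
    bout_fish: list = []
    bout_turns: list = []
    bout_disp: list = []
    bout_start_xy: list = []

    rand = rng.random
    normal = rng.normal
    dt = config.dt
    states = [
        AgentState(
            position=np.zeros(2),
            heading=0.0,
            body_length=config.body_length,
            body_height=config.body_height,
        )
        for _ in range(n)
    ]

    for t in range(n_steps):
        for i in range(n):
            if remaining[i] > 0:
                step = profile[bout_steps - remaining[i]]
                xs[i], ys[i], _ = _advance(xs[i], ys[i], uxs[i], uys[i], step, radius)
                remaining[i] -= 1
            elif rand() < hazard:
                # refresh lightweight state views for the decision
                for j in range(n):
                    st = states[j]
                    st.position[0] = xs[j]
                    st.position[1] = ys[j]
                    st.heading = hs[j]
                focal = states[i]
                others = [states[j] for j in range(n) if j != i]
                turn = decide_turn(focal, others, config, rng)
                hs[i] = _wrap_pi(hs[i] - turn)
                uxs[i] = math.cos(hs[i])
                uys[i] = math.sin(hs[i])
                bout_onsets.append(t * dt)
                bout_fish.append(i)
                bout_turns.append(turn)
                bout_start_xy.append((xs[i], ys[i]))
                remaining[i] = bout_steps
                # first displacement step happens this time step
                xs[i], ys[i], _ = _advance(
                    xs[i], ys[i], uxs[i], uys[i], profile[0], radius
                )
                remaining[i] -= 1
        positions[t + 1, :, 0] = xs
        positions[t + 1, :, 1] = ys
        headings[t + 1] = hs

    for (x0, y0), i, onset in zip(bout_start_xy, bout_fish, bout_onsets):
        k = min(n_steps, int(round(onset / dt)) + bout_steps)
        bout_disp.append(
            math.hypot(positions[k, i, 0] - x0, positions[k, i, 1] - y0)
        )

    bouts = pd.DataFrame(
        {
            "onset_s": np.asarray(bout_onsets, dtype=float),
            "fish_id": np.asarray(bout_fish, dtype=int),
            "turn_rad": np.asarray(bout_turns, dtype=float),
            "displacement_cm": np.asarray(bout_disp, dtype=float),
        }
    )
    return TrajectorySet(
        time=np.arange(T) * dt,
        positions=positions,
        headings=headings,
        bouts=bouts,
        dt=dt,
        age=config.age,
        variant=config.variant,
        arena_diameter=config.arena_diameter,
        body_length=config.body_length,
        body_height=config.body_height,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def batch_seeds(base_seed: int, n: int) -> list:
    """Deterministic per-repetition integer seeds below 2**31."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint32)]


@dataclass
class BatchResult:
    """A batch of repeated runs plus its group-statistics summary."""

    runs: list
    summary: dict
    config: SimulationConfig
    base_seed: int


def run_batch(
    config: SimulationConfig,
    n_reps: int = 50,
    base_seed: int = 0,
    n_shuffles: int = 1000,
    nn_stride: int = 5,
    progress: bool = False,
) -> BatchResult:
    """Run ``n_reps`` independent repetitions and summarize group structure.

    The summary reports the mean normalized dispersion of each repetition
    against the cross-repetition shuffled nearest-neighbor baseline, and the
    mean heading alignment.
    """
    from . import analysis

    seeds = batch_seeds(base_seed, n_reps)
    runs = []
    for k, s in enumerate(seeds):
        runs.append(run_simulation(config, seed=s))
        if progress:
            print(f"  rep {k + 1}/{n_reps}", flush=True)
    pools = [r.positions for r in runs]
    if n_reps >= config.n_agents:
        baseline = analysis.shuffled_nn1(
            pools, n_assemblies=n_shuffles, stride=nn_stride,
            seed=np.random.SeedSequence((base_seed, 0xD1F)),
        )
        disp = [
            analysis.group_dispersion(p[::nn_stride], baseline) for p in pools
        ]
    else:
        # too few repetitions for the cross-group shuffled baseline
        baseline = float("nan")
        disp = []
    align = [
        float(np.mean(analysis.alignment_from_headings(r.headings[::nn_stride])))
        for r in runs
    ]
    rate = len(pd.concat([r.bouts for r in runs])) / (
        n_reps * config.n_agents * config.duration
    )
    summary = {
        "age": config.age,
        "variant": config.variant,
        "n_reps": n_reps,
        "n_agents": config.n_agents,
        "duration_s": config.duration,
        "nn1_baseline_cm": float(baseline),
        "mean_dispersion": float(np.mean(disp)) if disp else float("nan"),
        "sd_dispersion": float(np.std(disp, ddof=1)) if len(disp) > 1 else 0.0,
        "per_rep_dispersion": disp,
        "mean_alignment": float(np.mean(align)),
        "bout_rate_hz": float(rate),
    }
    return BatchResult(runs=runs, summary=summary, config=config, base_seed=base_seed)
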