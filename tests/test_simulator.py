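"""Bout-based group simulator: decisions, bouts, runs and batches."""

import math

import numpy as np
import pytest

from shoalsim.responses import ResponseCurve
from shoalsim.simulate import (
    AgentState,
    SimulationConfig,
    decide_turn,
    execute_bout,
    run_simulation,
    social_turn_probability,
)

from conftest import make_agent


def sim_cfg(cfg, age=7, variant="nonsocial", **kw):
    return SimulationConfig.from_run_config(cfg, age, variant, **kw)


# ---------------------------------------------------------------------------
# decide_turn


def test_nonsocial_turn_direction_is_fair_coin(cfg):
    config = sim_cfg(cfg, variant="nonsocial")
    agent = make_agent((0.0, 0.0), 0.0)
    rng = np.random.default_rng(7)
    draws = np.array([decide_turn(agent, [], config, rng) for _ in range(10_000)])
    right_fraction = np.mean(draws > 0)
    assert right_fraction == pytest.approx(0.5, abs=0.015)  # 3 sigma


def test_wall_rule_ignores_neighbors(cfg):
    """Within 2 BL of the wall the turn is wall-driven: the same RNG stream
    yields identical decisions with and without a large nearby neighbor."""
    config = sim_cfg(cfg, variant="vr_social")
    radius = config.arena_diameter / 2.0
    # 1 BL from the wall, heading tangentially
    agent = make_agent((radius - config.body_length, 0.0), math.pi / 2)
    neighbor = make_agent((radius - 3 * config.body_length, 0.3), 0.0)
    with_nb = [
        decide_turn(agent, [neighbor], config, np.random.default_rng(s))
        for s in range(200)
    ]
    without = [
        decide_turn(agent, [], config, np.random.default_rng(s)) for s in range(200)
    ]
    assert with_nb == without


def test_wall_rule_turn_away_probability(cfg):
    config = sim_cfg(cfg, variant="nonsocial")
    radius = config.arena_diameter / 2.0
    # heading +x (outward): away from the wall is any turn towards -x,
    # i.e. the rightward/leftward split follows the wall curve
    agent = make_agent((radius - config.body_length, 0.0), math.pi / 2)
    # wall on the right of a fish heading +y at the +x wall -> away = left
    rng = np.random.default_rng(11)
    draws = np.array([decide_turn(agent, [], config, rng) for _ in range(20_000)])
    p_left = np.mean(draws < 0)
    assert p_left == pytest.approx(config.wall(1.0), abs=0.012)  # ~3.5 sigma


def test_vr_social_decision_matches_eq1_probability(cfg):
    """Monte-Carlo right-turn fraction matches the deterministic pipeline."""
    config = sim_cfg(cfg, variant="vr_social")
    agent = make_agent((0.0, 0.0), 0.0)
    neighbor = make_agent((0.3, 0.8), 1.0)  # large, on the left, mid-range
    p = social_turn_probability(agent, [neighbor], config)
    assert p > 0.5  # repulsive at 7 dpf
    rng = np.random.default_rng(5)
    draws = np.array(
        [decide_turn(agent, [neighbor], config, rng) for _ in range(20_000)]
    )
    frac = np.mean(draws > 0)
    sigma = math.sqrt(p * (1 - p) / 20_000)
    assert frac == pytest.approx(p, abs=3.5 * sigma)


def test_social_probability_mirror_symmetry(cfg):
    for variant in ("vr_social", "group_derived"):
        config = sim_cfg(cfg, age=14, variant=variant)
        agent = make_agent((0.0, 0.0), 0.0)
        nb_left = make_agent((0.5, 0.6), 0.3)
        nb_right = make_agent((0.5, -0.6), -0.3)
        p = social_turn_probability(agent, [nb_left], config)
        q = social_turn_probability(agent, [nb_right], config)
        assert q == pytest.approx(1.0 - p, abs=1e-12)
        both = social_turn_probability(agent, [nb_left, nb_right], config)
        assert both == pytest.approx(0.5, abs=1e-12)


def test_blind_zone_neighbor_has_no_influence(cfg):
    config = sim_cfg(cfg, variant="vr_social")
    agent = make_agent((0.0, 0.0), 0.0)
    behind = make_agent((-1.0, 0.0), 0.5)
    assert social_turn_probability(agent, [behind], config) == 0.5


# ---------------------------------------------------------------------------
# execute_bout


def test_straight_bout_displacement_equals_bout_size(cfg):
    config = sim_cfg(cfg)
    agent = make_agent((0.0, 0.0), 0.7)
    new, path = execute_bout(agent, 0.0, config)
    moved = np.hypot(*(new.position - agent.position))
    assert moved == pytest.approx(config.bout_size, abs=1e-12)
    assert new.heading == pytest.approx(0.7)
    assert len(path) == config.bout_steps
    # monotone progress along the heading
    along = path @ np.array([math.cos(0.7), math.sin(0.7)])
    assert np.all(np.diff(along) > 0)


def test_bout_truncated_at_wall(cfg):
    config = sim_cfg(cfg)
    radius = config.arena_diameter / 2.0
    agent = make_agent((radius - 0.05, 0.0), 0.0)  # aimed straight at the wall
    new, path = execute_bout(agent, 0.0, config)
    assert np.hypot(*new.position) <= radius + 1e-12
    assert np.all(np.hypot(path[:, 0], path[:, 1]) <= radius + 1e-12)


def test_turn_sign_rotates_heading_clockwise(cfg):
    config = sim_cfg(cfg)
    agent = make_agent((0.0, 0.0), 0.0)
    new, _ = execute_bout(agent, math.radians(30.0), config)  # rightward
    assert new.heading == pytest.approx(-math.radians(30.0))


# ---------------------------------------------------------------------------
# run_simulation


def test_same_seed_bit_identical(cfg):
    config = sim_cfg(cfg, variant="vr_social", duration=30.0)
    a = run_simulation(config, seed=9)
    b = run_simulation(config, seed=9)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.headings, b.headings)
    assert a.bouts.equals(b.bouts)


def test_positions_stay_inside_arena(short_run):
    r = np.hypot(short_run.positions[..., 0], short_run.positions[..., 1])
    assert r.max() <= short_run.arena_diameter / 2.0 + 1e-9


def test_bout_count_follows_configured_rate(cfg):
    config = sim_cfg(cfg, variant="nonsocial", duration=600.0)
    traj = run_simulation(config, seed=3)
    expected = config.bout_rate * config.duration * config.n_agents
    assert len(traj.bouts) == pytest.approx(expected, abs=3 * math.sqrt(expected))


def test_flat_curve_social_reduces_to_nonsocial(cfg):
    """Zeroing all social biases makes the social variant reproduce the
    non-social one exactly under the same seed."""
    flat = ResponseCurve(age=7, anchors=((0.0, 0.5), (90.0, 0.5)))
    social = sim_cfg(cfg, variant="vr_social", duration=60.0, curve=flat)
    plain = sim_cfg(cfg, variant="nonsocial", duration=60.0)
    a = run_simulation(social, seed=21)
    b = run_simulation(plain, seed=21)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.headings, b.headings)


def test_rotational_symmetry(cfg):
    """Rotating the initial conditions rotates the whole output: the
    decision rule depends only on relative geometry."""
    config = sim_cfg(cfg, variant="vr_social", duration=30.0)
    rng = np.random.default_rng(17)
    pos0 = rng.uniform(-1.5, 1.5, size=(config.n_agents, 2))
    hdg0 = rng.uniform(-np.pi, np.pi, size=config.n_agents)
    theta = 1.1
    R = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    a = run_simulation(config, seed=4, initial_positions=pos0,
                       initial_headings=hdg0)
    b = run_simulation(config, seed=4, initial_positions=pos0 @ R.T,
                       initial_headings=hdg0 + theta)
    assert np.allclose(b.positions, a.positions @ R.T, atol=1e-9)
    da = np.exp(1j * a.headings)
    db = np.exp(1j * b.headings)
    assert np.allclose(db, da * np.exp(1j * theta), atol=1e-9)


def test_invalid_config_rejected_before_stepping(cfg):
    config = sim_cfg(cfg, n_agents=0)
    with pytest.raises(ValueError):
        run_simulation(config, seed=0)
    with pytest.raises(ValueError):
        SimulationConfig.from_run_config(cfg, 7, "telepathic")
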