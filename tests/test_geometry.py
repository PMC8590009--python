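"""Retinal geometry: eye assignment, ray casting, occupancy, pinhole model."""

import math

import numpy as np
import pytest

from shoalsim.geometry import (
    BLIND_ZONE_DEG,
    RAY_SPAN_DEG,
    BodyOutline,
    RetinaParams,
    assign_eye,
    cast_rays,
    eye_extents_timeseries,
    horizontal_extent,
    project_point_to_retina,
    retinal_image_of_disc,
    vertical_occupancy,
)

from conftest import make_agent


def rect(center, angle, length=0.4, width=0.1, height=0.2):
    u = np.array([math.cos(angle), math.sin(angle)])
    c = np.asarray(center, dtype=float)
    return BodyOutline(
        head=c + u * length / 2, tail=c - u * length / 2, width=width, height=height
    )


# ---------------------------------------------------------------------------
# eye assignment


@pytest.mark.parametrize(
    "point, expected_eye, expected_bearing",
    [
        ((1.0, 0.0), "right", 0.0),     # dead ahead: tie-break right
        ((-1.0, 0.0), "blind", 180.0),  # directly behind
        ((0.0, -1.0), "right", 90.0),   # 90 deg on the right
        ((0.0, 1.0), "left", 90.0),
        ((-1.0, 0.02), "blind", None),  # just inside the rear blind cone
    ],
)
def test_assign_eye(agent, point, expected_eye, expected_bearing):
    eye, bearing = assign_eye(agent, point)
    assert eye == expected_eye
    if expected_bearing is not None:
        assert bearing == pytest.approx(expected_bearing)


def test_assign_eye_rejects_coincident_point(agent):
    with pytest.raises(ValueError):
        assign_eye(agent, (0.0, 0.0))


def test_field_geometry_covers_the_circle():
    # two 165-deg fields plus the rear blind zone tile the full 360
    assert 2 * RAY_SPAN_DEG + BLIND_ZONE_DEG == 360.0


# ---------------------------------------------------------------------------
# vertical occupancy


def test_vertical_occupancy_values():
    assert vertical_occupancy(0.0, 1.0) == 0.0
    assert vertical_occupancy(1.0, 1.0) == pytest.approx(90.0)
    # direct evaluation of 2*arctan(0.2/1.0)
    assert vertical_occupancy(0.2, 1.0) == pytest.approx(22.6198649, abs=1e-6)
    with pytest.raises(ValueError):
        vertical_occupancy(0.2, 0.0)


def test_vertical_occupancy_monotonicity():
    d = np.linspace(0.5, 5.0, 40)
    v = [vertical_occupancy(0.25, x) for x in d]
    assert np.all(np.diff(v) < 0)
    h = np.linspace(0.0, 1.0, 40)
    v = [vertical_occupancy(x, 2.0) for x in h]
    assert np.all(np.diff(v) > 0)


# ---------------------------------------------------------------------------
# horizontal extent


def test_horizontal_extent_broadside_closed_form(agent):
    # neighbor of length L broadside at perpendicular distance d, centered
    L, d = 0.4, 1.5
    nb = rect((d, 0.0), math.pi / 2, length=L)
    expected = math.degrees(2 * math.atan(L / (2 * d)))
    assert horizontal_extent(agent, nb) == pytest.approx(expected, abs=1e-9)


def test_horizontal_extent_end_on_is_zero(agent):
    nb = rect((2.0, 0.0), 0.0)  # collinear with the line of sight
    assert horizontal_extent(agent, nb) == pytest.approx(0.0, abs=1e-9)


def test_horizontal_extent_decreases_with_distance(agent):
    vals = [horizontal_extent(agent, rect((d, 0.3), math.pi / 2)) for d in
            np.linspace(1.0, 6.0, 20)]
    assert np.all(np.diff(vals) < 0)


# ---------------------------------------------------------------------------
# ray casting


def test_ray_spacing(agent):
    occ = cast_rays(agent, [rect((1.0, 1.0), 0.0)], n_rays=1000)
    assert occ.ray_spacing == pytest.approx(0.165)


def test_blind_zone_neighbor_invisible(agent):
    occ = cast_rays(agent, [rect((-2.0, 0.0), math.pi / 2, length=0.2, width=0.05)])
    assert occ.total_left == 0.0
    assert occ.total_right == 0.0
    assert occ.sigma == 0.0


def test_empty_neighbor_list_is_zero_occupancy(agent):
    occ = cast_rays(agent, [])
    assert occ.sigma == 0.0
    assert occ.intervals == {"left": [], "right": []}


def _brute_force_totals(focal, outlines, n_rays, span_deg=RAY_SPAN_DEG):
    """Independent oracle: explicit ray-edge intersection at fine sampling."""
    spacing = span_deg / n_rays
    offsets = np.radians((np.arange(n_rays) + 0.5) * spacing)
    totals = {}
    o = np.asarray(focal.position, dtype=float)
    for eye, sign in (("left", 1.0), ("right", -1.0)):
        ang = focal.heading + sign * offsets
        d = np.stack([np.cos(ang), np.sin(ang)], axis=1)  # (R, 2)
        hit = np.zeros(n_rays, dtype=bool)
        for outline in outlines:
            corners = outline.corners()
            for k in range(4):
                p0 = corners[k]
                p1 = corners[(k + 1) % 4]
                e = p1 - p0
                w = p0 - o
                denom = d[:, 0] * e[1] - d[:, 1] * e[0]
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = (w[0] * e[1] - w[1] * e[0]) / denom
                    s = (w[0] * d[:, 1] - w[1] * d[:, 0]) / denom
                ok = (np.abs(denom) > 1e-14) & (t >= 0) & (s >= 0) & (s <= 1)
                hit |= ok
        totals[eye] = hit.sum() * spacing
    return totals


def test_cast_rays_matches_fine_ray_oracle():
    """Two disjoint neighbors on one eye: totals equal the sum of the
    individual extents and agree with a 100 000-ray brute-force recount."""
    focal = make_agent(heading=0.3)
    nb1 = rect((1.0, 1.2), 0.7)
    nb2 = rect((2.0, -0.5), -0.4)
    occ = cast_rays(focal, [nb1, nb2], n_rays=1000)
    oracle = _brute_force_totals(focal, [nb1, nb2], n_rays=100_000)
    assert occ.total_left == pytest.approx(oracle["left"], abs=occ.ray_spacing)
    assert occ.total_right == pytest.approx(oracle["right"], abs=occ.ray_spacing)
    # disjoint bodies: union equals the sum of per-neighbor extents
    per_eye_sums = {
        eye: sum(e[eye] for e in occ.neighbor_extents) for eye in ("left", "right")
    }
    assert occ.total_left == pytest.approx(per_eye_sums["left"], abs=occ.ray_spacing)
    assert occ.total_right == pytest.approx(per_eye_sums["right"], abs=occ.ray_spacing)


def test_cast_rays_convergence_and_bounds(agent):
    neighbors = [rect((0.8, 0.6), 1.0), rect((-0.2, 1.5), 2.0)]
    prev = cast_rays(agent, neighbors, n_rays=500)
    for n in (1000, 2000, 4000):
        occ = cast_rays(agent, neighbors, n_rays=n)
        assert occ.total_left <= RAY_SPAN_DEG and occ.total_right <= RAY_SPAN_DEG
        for e_prev, e_new in zip(prev.neighbor_extents, occ.neighbor_extents):
            for eye in ("left", "right"):
                assert abs(e_prev[eye] - e_new[eye]) <= RAY_SPAN_DEG / (n // 2)
        prev = occ


def test_cast_rays_totals_equal_interval_measure(agent):
    occ = cast_rays(agent, [rect((1.0, 0.5), 0.5), rect((1.1, 0.7), 0.2)])
    for eye, total in (("left", occ.total_left), ("right", occ.total_right)):
        measure = sum(b - a for a, b in occ.intervals[eye])
        assert total == pytest.approx(measure, abs=1e-9)
        assert total >= 0


def test_eye_extents_timeseries_matches_scalar():
    """The vectorized occupancy used by the analyzer agrees with the
    head/tail bearing extents computed one neighbor at a time."""
    L = 0.4
    # fully visible neighbors: per-eye sums equal the head/tail extents
    pos = np.array([[[0.0, 0.0], [1.0, 0.8], [1.5, -0.6]]])
    hdg = np.array([[0.0, 1.0, -0.5]])
    left, right = eye_extents_timeseries(pos, hdg, L)
    focal = make_agent(pos[0, 0], 0.0)
    expected = sum(
        horizontal_extent(focal, rect(pos[0, j], hdg[0, j], length=L))
        for j in (1, 2)
    )
    assert left[0, 0] + right[0, 0] == pytest.approx(expected, abs=1e-9)
    # a neighbor dead behind the focal fish contributes nothing
    pos_b = np.array([[[0.0, 0.0], [-2.0, 0.0]]])
    hdg_b = np.array([[0.0, np.pi / 2]])
    lb, rb = eye_extents_timeseries(pos_b, hdg_b, 0.2)
    assert lb[0, 0] == 0.0 and rb[0, 0] == 0.0
    # a rigid rotation of the whole scene leaves occupancy unchanged
    theta = 0.85
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    lrot, rrot = eye_extents_timeseries(pos @ R.T, hdg + theta, L)
    assert lrot[0, 0] == pytest.approx(left[0, 0], abs=1e-9)
    assert rrot[0, 0] == pytest.approx(right[0, 0], abs=1e-9)


# ---------------------------------------------------------------------------
# pinhole retina model


def test_projection_on_optical_axis_is_origin(agent):
    params = RetinaParams()
    # a point along the right eye's optical axis at eye height
    axis = agent.heading - math.radians(90.0 - params.vergence_deg / 2.0)
    eye_center = np.array([0.0, -params.eye_separation / 2.0])
    p = eye_center + 3.0 * np.array([math.cos(axis), math.sin(axis)])
    coord = project_point_to_retina(params, agent, (p[0], p[1], params.eye_height),
                                    eye="right")
    assert coord.azimuth_deg == pytest.approx(0.0, abs=1e-9)
    assert coord.elevation_deg == pytest.approx(0.0, abs=1e-9)
    assert coord.in_field


def test_projection_floor_point_elevation(agent):
    """A floor point at the optical-axis azimuth sits at elevation
    -arctan(h / horizontal distance)."""
    params = RetinaParams()
    axis = agent.heading + math.radians(90.0 - params.vergence_deg / 2.0)
    eye_center = np.array([0.0, params.eye_separation / 2.0])
    dist = 2.5
    p = eye_center + dist * np.array([math.cos(axis), math.sin(axis)])
    coord = project_point_to_retina(params, agent, p, eye="left")
    assert coord.azimuth_deg == pytest.approx(0.0, abs=1e-9)
    expected = -math.degrees(math.atan(params.eye_height / dist))
    assert coord.elevation_deg == pytest.approx(expected, abs=1e-9)


def test_projection_mirror_symmetry_about_horizon(agent):
    params = RetinaParams()
    hi = project_point_to_retina(params, agent, (1.0, 1.5, params.eye_height + 0.3),
                                 eye="left")
    lo = project_point_to_retina(params, agent, (1.0, 1.5, params.eye_height - 0.3),
                                 eye="left")
    assert hi.azimuth_deg == pytest.approx(lo.azimuth_deg)
    assert hi.elevation_deg == pytest.approx(-lo.elevation_deg)


def test_disc_image_degenerate_and_small_angle(agent):
    params = RetinaParams()
    img0 = retinal_image_of_disc(params, agent, (1.0, 1.0), diameter=0.0)
    assert img0.width_deg == 0.0 and img0.height_deg == 0.0

    # small disc far away: width ~ 2*arctan(D/2d)
    D, center = 0.2, np.array([2.0, 2.0])
    img = retinal_image_of_disc(params, agent, center, diameter=D, eye="left")
    d = np.hypot(*(center - np.array([0.0, params.eye_separation / 2.0])))
    expected = math.degrees(2 * math.atan(D / (2 * d)))
    assert img.width_deg == pytest.approx(expected, rel=0.10)
    # doubling the boundary sampling changes the extents by < 0.1 deg
    img2 = retinal_image_of_disc(params, agent, center, diameter=D, n_boundary=128,
                                 eye="left")
    assert abs(img2.width_deg - img.width_deg) < 0.1
    assert abs(img2.height_deg - img.height_deg) < 0.1
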