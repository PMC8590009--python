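"""Retinal geometry: what neighbors occupy on each eye of a focal fish.

Larval zebrafish have laterally placed eyes, each covering a wide visual
field.  Following the ray-casting convention used throughout this package,
each eye spans 165 degrees measured from the direction of motion backwards,
leaving a 30 degree blind zone behind the animal.  Horizontal occupancy of a
neighbor is the angular extent its body subtends in the horizontal plane;
vertical occupancy is the angular height of its image, ``2*arctan(H/d)`` for
a neighbor of height ``H`` at distance ``d``.

Angles at every public interface are in degrees; positions are in cm.
Bearings are measured from the focal heading, with eye-local angles running
from 0 (straight ahead) to the rear edge of the eye's field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

RAY_SPAN_DEG = 165.0
"""Per-eye angular span used for ray casting (deg)."""

BLIND_ZONE_DEG = 360.0 - 2.0 * RAY_SPAN_DEG
"""Blind angle behind the fish (deg)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BodyOutline:
    """A neighbor's body for occupancy purposes: a rectangle on its body axis.

    The rectangle has length ``|head - tail|`` and the given width, centered
    on the segment from tail to head.  ``height`` is the body height used for
    vertical occupancy.
    """

    head: np.ndarray
    tail: np.ndarray
    width: float
    height: float

    def __post_init__(self):
        object.__setattr__(self, "head", np.asarray(self.head, dtype=float))
        object.__setattr__(self, "tail", np.asarray(self.tail, dtype=float))
        if self.width <= 0:
            raise ValueError("BodyOutline.width must be positive")
        if self.height <= 0:
            raise ValueError("BodyOutline.height must be positive")
        if np.allclose(self.head, self.tail):
            raise ValueError("BodyOutline head and tail must be distinct")

    @property
    def centroid(self) -> np.ndarray:
        return 0.5 * (self.head + self.tail)

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.head - self.tail)))

    def corners(self) -> np.ndarray:
        """Four rectangle corners, shape (4, 2), counter-clockwise."""
        axis = self.head - self.tail
        u = axis / np.hypot(*axis)
        w = np.array([-u[1], u[0]]) * (self.width / 2.0)
        return np.array(
            [self.tail - w, self.head - w, self.head + w, self.tail + w]
        )


@dataclass(frozen=True)
class RetinaParams:
    """Pinhole-retina parameters of the larva (lengths in cm)."""

    eye_separation: float = 0.12
    eye_radius: float = 0.045
    eye_height: float = 0.5
    effective_field_deg: float = 163.0
    vergence_deg: float = 36.0

    def __post_init__(self):
        for name in ("eye_separation", "eye_radius", "eye_height",
                     "effective_field_deg", "vergence_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RetinaParams.{name} must be positive")
        if self.effective_field_deg > 180.0:
            raise ValueError("RetinaParams.effective_field_deg must be <= 180")


@dataclass(frozen=True)
class RetinalCoordinate:
    """Angular position of an image relative to the back-of-retina center
    (azimuth) and the horizon line (elevation), in degrees.

    ``in_field`` is False when the source point lies outside the effective
    retinal field (including points behind the pinhole plane).
    """

    azimuth_deg: float
    elevation_deg: float
    in_field: bool = True


@dataclass
class RetinalOccupancyMap:
    """Per-eye angular occupancy of a focal fish at one instant.

    ``intervals`` maps eye label to a list of ``(start_deg, end_deg)``
    occupied intervals in eye-local coordinates (0 = straight ahead,
    increasing towards the rear of that eye's field).  ``neighbor_extents``
    holds, for each neighbor in input order, the occupied extent on each eye
    in degrees.  The sign convention of ``delta``: negative values mean
    higher occupancy on the *left* eye.
    """

    intervals: dict = field(default_factory=lambda: {"left": [], "right": []})
    neighbor_extents: list = field(default_factory=list)
    total_left: float = 0.0
    total_right: float = 0.0
    n_rays: int = 1000
    span_deg: float = RAY_SPAN_DEG

    @property
    def delta(self) -> float:
        """Occupancy difference between the eyes (deg); negative = more on the left."""
        return self.total_right - self.total_left

    @property
    def sigma(self) -> float:
        """Summed occupancy over both eyes (deg)."""
        return self.total_left + self.total_right

    @property
    def ray_spacing(self) -> float:
        return self.span_deg / self.n_rays


@dataclass
class DiscImage:
    """Retinal image of a floor-projected disc."""

    width_deg: float
    height_deg: float
    center: RetinalCoordinate
    truncated: bool


# ---------------------------------------------------------------------------
# helpers


def _wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = (-a + 180.0) % 360.0
    out = 180.0 - out
    if out.ndim == 0:
        return float(out)
    return out


def signed_bearing_deg(focal, point) -> float:
    """Signed bearing of ``point`` from the focal heading, in (-180, 180].

    Positive bearings are on the left of the heading (counter-clockwise),
    negative on the right.
    """
    pos = np.asarray(focal.position, dtype=float)
    p = np.asarray(point, dtype=float)[:2]
    d = p - pos
    if not np.any(d):
        raise ValueError("point coincides with the focal position; bearing undefined")
    ang = math.degrees(math.atan2(d[1], d[0]))
    return _wrap_deg(ang - math.degrees(focal.heading))


# ---------------------------------------------------------------------------
# operations


def assign_eye(focal, point, span_deg: float = RAY_SPAN_DEG):
    """Assign a point to an eye of the focal fish.

    Returns ``(eye, bearing_deg)`` where ``eye`` is ``"left"``, ``"right"``
    or ``"blind"`` and ``bearing_deg`` is the unsigned bearing from the
    heading.  Points dead ahead (bearing 0) tie-break to the right eye;
    bearings beyond ``span_deg`` fall in the blind zone behind the fish.
    """
    b = signed_bearing_deg(focal, point)
    mag = abs(b)
    if mag > span_deg:
        return "blind", mag
    if b > 0:
        return "left", mag
    return "right", mag


def vertical_occupancy(height: float, distance: float) -> float:
    """Vertical angular occupancy ``2*arctan(H/d)`` in degrees.

    The full body height enters the arctangent argument, matching the
    convention used by the simulation models in this package.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if height < 0:
        raise ValueError("height must be non-negative")
    return math.degrees(2.0 * math.atan(height / distance))


def horizontal_extent(focal, neighbor: BodyOutline) -> float:
    """Unsigned angle (deg) between the bearings to a neighbor's head and tail."""
    pos = np.asarray(focal.position, dtype=float)
    a = neighbor.head - pos
    b = neighbor.tail - pos
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0 or nb == 0:
        raise ValueError("neighbor head or tail coincides with the focal position")
    cross = a[0] * b[1] - a[1] * b[0]
    dot = a[0] * b[0] + a[1] * b[1]
    return abs(math.degrees(math.atan2(cross, dot)))


def _corner_interval(focal, outline: BodyOutline):
    """Signed-bearing interval (lo, hi) subtended by a convex outline.

    For a focal point outside the polygon the hit set of ray directions is a
    single arc narrower than 180 deg: the interval between the extreme corner
    bearings.  The interval is expressed in unwrapped signed bearings and may
    extend past +-180 when the body sits behind the fish.
    """
    pos = np.asarray(focal.position, dtype=float)
    corners = outline.corners()
    d = corners - pos
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) - math.degrees(focal.heading)
    ang = _wrap_deg(ang)
    ref = ang[0]
    rel = _wrap_deg(ang - ref)
    lo = ref + rel.min()
    hi = ref + rel.max()
    return lo, hi


def _interval_eye_overlap(lo: float, hi: float, span_deg: float):
    """Occupied sub-intervals of a bearing interval on each eye field.

    Returns ``{'left': [(a, b), ...], 'right': [...]}`` in eye-local
    coordinates (0 ahead, ``span_deg`` rearmost).  The left field covers
    signed bearings (0, span]; the right field [-span, 0).  Shifted copies of
    the interval handle bodies straddling the rear +-180 seam.
    """
    out = {"left": [], "right": []}
    for shift in (-360.0, 0.0, 360.0):
        a, b = lo + shift, hi + shift
        # left eye: signed bearings [0, span] map to eye-local [0, span]
        la, lb = max(a, 0.0), min(b, span_deg)
        if lb > la:
            out["left"].append((la, lb))
        # right eye: signed bearings [-span, 0] map to eye-local [0, span]
        ra, rb = max(a, -span_deg), min(b, 0.0)
        if rb > ra:
            out["right"].append((-rb, -ra))
    return out


def cast_rays(
    focal,
    neighbors: Sequence[BodyOutline],
    n_rays: int = 1000,
    span_deg: float = RAY_SPAN_DEG,
) -> RetinalOccupancyMap:
    """Ray-cast angular occupancy of neighbors on both eyes.

    ``n_rays`` rays per eye span ``span_deg`` from the heading backwards; the
    angular spacing is ``span_deg / n_rays``.  Each neighbor is a rectangle
    (length head-to-tail, given width); a ray counts as hit when its bearing
    falls inside the neighbor's subtended arc.  Per-neighbor extents are
    ``hits * spacing`` and eye totals are the measure of the union of hit
    rays, so overlapping neighbors are not double counted in the totals.
    """
    if n_rays < 2:
        raise ValueError("n_rays must be >= 2")
    spacing = span_deg / n_rays
    # ray bearings at bin midpoints, eye-local
    offsets = (np.arange(n_rays) + 0.5) * spacing
    hit_any = {"left": np.zeros(n_rays, bool), "right": np.zeros(n_rays, bool)}
    neighbor_extents = []
    for nb in neighbors:
        lo, hi = _corner_interval(focal, nb)
        per_eye = {"left": 0.0, "right": 0.0}
        for eye, ivs in _interval_eye_overlap(lo, hi, span_deg).items():
            hit = np.zeros(n_rays, bool)
            for a, b in ivs:
                hit |= (offsets >= a) & (offsets <= b)
            per_eye[eye] = float(hit.sum()) * spacing
            hit_any[eye] |= hit
        neighbor_extents.append(per_eye)

    intervals = {"left": [], "right": []}
    totals = {}
    for eye in ("left", "right"):
        mask = hit_any[eye]
        totals[eye] = float(mask.sum()) * spacing
        # contiguous runs of hit rays -> occupied intervals
        idx = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(int)))
        for start, stop in zip(idx[::2], idx[1::2]):
            intervals[eye].append((start * spacing, stop * spacing))

    return RetinalOccupancyMap(
        intervals=intervals,
        neighbor_extents=neighbor_extents,
        total_left=totals["left"],
        total_right=totals["right"],
        n_rays=n_rays,
        span_deg=span_deg,
    )


# ---------------------------------------------------------------------------
# pinhole retina model


def _eye_geometry(params: RetinaParams, focal, eye: str):
    """World-frame eye center (3-D) and optical-axis azimuth (rad)."""
    h = focal.heading
    side = 1.0 if eye == "left" else -1.0
    perp = np.array([-math.sin(h), math.cos(h)]) * side
    center = np.asarray(focal.position, dtype=float) + perp * (
        params.eye_separation / 2.0
    )
    # optical axis rotated outward from the heading by (90 - vergence/2)
    axis = h + side * math.radians(90.0 - params.vergence_deg / 2.0)
    return np.array([center[0], center[1], params.eye_height]), axis


def project_point_to_retina(
    params: RetinaParams, focal, point, eye: str | None = None
) -> RetinalCoordinate:
    """Project a world point through the eye's pinhole onto the retina.

    The pinhole sits at the eye-sphere center; the image forms on the back
    hemisphere, so the image's angular position about the back-of-retina
    center equals the direction to the source point about the optical axis.
    ``point`` is ``(x, y)`` on the floor plane or ``(x, y, z)`` in cm.
    Points outside the effective field (including behind the pinhole plane)
    come back flagged ``in_field=False``.
    """
    p = np.asarray(point, dtype=float)
    if p.size == 2:
        p = np.array([p[0], p[1], 0.0])
    if eye is None:
        lbl, _ = assign_eye(focal, p[:2], span_deg=180.0)
        eye = "right" if lbl != "left" else "left"
    eye_c, axis = _eye_geometry(params, focal, eye)
    rel = p - eye_c
    horiz = math.hypot(rel[0], rel[1])
    if horiz == 0 and rel[2] == 0:
        raise ValueError("point coincides with the eye center")
    az = _wrap_deg(math.degrees(math.atan2(rel[1], rel[0])) - math.degrees(axis))
    el = math.degrees(math.atan2(rel[2], horiz))
    half = params.effective_field_deg / 2.0
    in_field = abs(az) <= half and abs(el) <= half
    return RetinalCoordinate(az, el, in_field)


def retinal_image_of_disc(
    params: RetinaParams,
    focal,
    center,
    diameter: float,
    n_boundary: int = 64,
    eye: str | None = None,
) -> DiscImage:
    """Angular width/height and center of a floor disc's retinal image.

    The disc boundary is sampled at ``n_boundary`` points (>= 64), each
    projected through the pinhole; the image extents are the azimuthal and
    elevational spans of the projected boundary.  ``truncated`` flags discs
    partially outside the effective field.
    """
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    n_boundary = max(int(n_boundary), 64)
    c = np.asarray(center, dtype=float)[:2]
    if diameter == 0:
        pt = project_point_to_retina(params, focal, c, eye=eye)
        return DiscImage(0.0, 0.0, pt, truncated=not pt.in_field)
    phi = np.linspace(0.0, 2.0 * math.pi, n_boundary, endpoint=False)
    pts = c + (diameter / 2.0) * np.c_[np.cos(phi), np.sin(phi)]
    coords = [project_point_to_retina(params, focal, p, eye=eye) for p in pts]
    az = np.array([c_.azimuth_deg for c_ in coords])
    el = np.array([c_.elevation_deg for c_ in coords])
    truncated = not all(c_.in_field for c_ in coords)
    center_coord = RetinalCoordinate(
        float((az.max() + az.min()) / 2.0),
        float((el.max() + el.min()) / 2.0),
        in_field=not truncated,
    )
    return DiscImage(
        float(az.max() - az.min()), float(el.max() - el.min()), center_coord, truncated
    )


# ---------------------------------------------------------------------------
# vectorized occupancy over trajectories (used by the analyzer)


def eye_extents_timeseries(positions, headings, body_length, span_deg=RAY_SPAN_DEG):
    """Total horizontal occupancy per eye for every fish at every time point.

    ``positions``: array (T, N, 2); ``headings``: (T, N) radians.  Each
    neighbor contributes the unsigned angle between the bearings to its head
    and tail (body length ``body_length`` along its heading), clipped to the
    two eye fields.  Returns ``(total_left, total_right)`` arrays of shape
    (T, N) in degrees.
    """
    pos = np.asarray(positions, dtype=float)
    hd = np.asarray(headings, dtype=float)
    T, N, _ = pos.shape
    u = np.stack([np.cos(hd), np.sin(hd)], axis=-1)  # (T, N, 2)
    half = 0.5 * body_length
    head = pos + half * u
    tail = pos - half * u

    def _bearings(target):
        # bearing of target[j] from focal i: (T, N_focal, N_target)
        d = target[:, None, :, :] - pos[:, :, None, :]
        ang = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
        return _wrap_deg(ang - np.degrees(hd)[:, :, None])

    b1 = _bearings(head)
    b2 = _bearings(tail)
    # unwrapped interval [lo, hi] around b1 (arc < 180 for exterior points)
    drel = _wrap_deg(b2 - b1)
    lo = b1 + np.minimum(drel, 0.0)
    hi = b1 + np.maximum(drel, 0.0)

    left = np.zeros_like(lo)
    right = np.zeros_like(lo)
    for shift in (-360.0, 0.0, 360.0):
        a, b = lo + shift, hi + shift
        left += np.clip(np.minimum(b, span_deg) - np.maximum(a, 0.0), 0.0, None)
        right += np.clip(np.minimum(b, 0.0) - np.maximum(a, -span_deg), 0.0, None)
    eye = np.eye(N, dtype=bool)
    left[:, eye] = 0.0
    right[:, eye] = 0.0
    return left.sum(axis=2), right.sum(axis=2)
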