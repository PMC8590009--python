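"""Visuomotor response functions and their combination rules.

The behavioural core of the model: an age-specific curve mapping the
vertical retinal occupancy of a stimulus (deg) to the probability of turning
away from / towards it, plus the rules for combining several stimuli --
weighted averaging of response biases within an eye and linear summation of
the signed per-eye averages across eyes, clipped once to [0, 1].

Conventions
-----------
* Curves are stored in the *left-stimulus* frame: ``p`` is the probability
  of turning RIGHT given the stimulus sits on the LEFT eye.  ``p > 0.5``
  therefore means repulsion, ``p < 0.5`` attraction.
* ``bias(v) = p(turn right | v) - 0.5``; positive = rightward tendency.
  A right-eye stimulus mirrors the sign.
* The occupancy difference between the eyes, ``delta``, is negative when
  the left eye is more occupied.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: default piecewise-linear anchors (v_deg, p) per age, honouring the
#: qualitative constraints measured in closed-loop assays: no response below
#: 6 deg at 7 dpf; an attraction dip crossing chance at exactly 11 deg at
#: 14 dpf; attraction persisting through 45 deg with a chance crossing at
#: 52 deg at 21 dpf.  Values beyond the last anchor hold constant.
DEFAULT_VR_ANCHORS = {
    7: [(0.0, 0.5), (6.0, 0.5), (60.0, 0.75)],
    14: [(0.0, 0.5), (6.0, 0.4), (11.0, 0.5), (60.0, 0.75)],
    21: [(0.0, 0.5), (25.0, 0.35), (52.0, 0.5), (90.0, 0.7)],
}

AGES = (7, 14, 21)


def _interp_hold(x: float, xs: Sequence[float], ys: Sequence[float]) -> float:
    """Scalar piecewise-linear interpolation with constant extrapolation."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    i = bisect.bisect_right(xs, x)
    x0, x1 = xs[i - 1], xs[i]
    y0, y1 = ys[i - 1], ys[i]
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0)


@dataclass(frozen=True)
class ResponseCurve:
    """Age-specific turn-probability curve vs. vertical occupancy.

    ``anchors`` are ``(v_deg, p)`` pairs, strictly increasing in ``v``,
    interpolated piecewise-linearly and held constant beyond the last anchor.
    Probabilities are in the left-stimulus frame (see module docstring).
    """

    age: int
    anchors: tuple = ()

    def __post_init__(self):
        anchors = tuple((float(v), float(p)) for v, p in self.anchors)
        if not anchors:
            anchors = tuple(DEFAULT_VR_ANCHORS[self.age])
        vs = [a[0] for a in anchors]
        ps = [a[1] for a in anchors]
        if any(v1 <= v0 for v0, v1 in zip(vs, vs[1:])):
            raise ValueError("ResponseCurve anchors must be strictly increasing in v")
        if vs[0] < 0:
            raise ValueError("ResponseCurve anchors must have v >= 0")
        if any(not 0.0 <= p <= 1.0 for p in ps):
            raise ValueError("ResponseCurve probabilities must lie in [0, 1]")
        object.__setattr__(self, "anchors", anchors)
        object.__setattr__(self, "_vs", vs)
        object.__setattr__(self, "_ps", ps)

    def __call__(self, v):
        """p(turn right | vertical occupancy v on the left eye)."""
        if np.ndim(v) == 0:
            return self.probability(float(v))
        v = np.asarray(v, dtype=float)
        if np.any(v < 0):
            raise ValueError("vertical occupancy must be non-negative")
        return np.interp(v, self._vs, self._ps)

    def probability(self, v: float) -> float:
        if v < 0:
            raise ValueError("vertical occupancy must be non-negative")
        return _interp_hold(v, self._vs, self._ps)

    def bias(self, v: float, side: str = "left") -> float:
        """Signed rightward bias for a stimulus of size ``v`` on ``side``."""
        b = self.probability(v) - 0.5
        if side == "left":
            return b
        if side == "right":
            return -b
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def turn_probability(curve: ResponseCurve, v: float) -> float:
    """Functional alias for :meth:`ResponseCurve.probability`."""
    return curve.probability(v)


def bias(curve: ResponseCurve, v: float, side: str = "left") -> float:
    """Functional alias for :meth:`ResponseCurve.bias`."""
    return curve.bias(v, side)


def _weights(vs: Sequence[float], age: int) -> list:
    """Within-eye weights: size-proportional at 7 dpf, equal at 14/21 dpf."""
    n = len(vs)
    if age == 7:
        tot = float(sum(vs))
        if tot <= 0:
            return [1.0 / n] * n
        return [v / tot for v in vs]
    return [1.0 / n] * n


def monocular_combine(stimuli: Iterable[tuple], age: int) -> float:
    """Predicted p(turn right) for several stimuli on one eye.

    ``stimuli`` is an iterable of ``(v_deg, bias)`` pairs, all on the same
    eye and already carrying their signs.  The prediction is the weighted
    average of the biases plus 0.5, with weights ``v_i / sum(v)`` at 7 dpf
    and ``1/N`` at 14 and 21 dpf.  An empty list is the no-stimulus neutral
    0.5.
    """
    stimuli = list(stimuli)
    if not stimuli:
        return 0.5
    vs = [s[0] for s in stimuli]
    bs = [s[1] for s in stimuli]
    w = _weights(vs, age)
    return min(1.0, max(0.0, 0.5 + sum(wi * bi for wi, bi in zip(w, bs))))


def binocular_combine(bias_left_eye: float, bias_right_eye: float) -> float:
    """Linear summation of the per-eye signed biases, clipped to [0, 1].

    ``p = clip(0.5 + bias_left + bias_right)``.  With equally strong
    opposing stimuli the biases cancel and the fish is equally likely to
    turn either way (winner-take-all by a fair draw, never a forward-swim
    average).
    """
    return min(1.0, max(0.0, 0.5 + bias_left_eye + bias_right_eye))


def eq1_turn_probability(
    left_vs: Sequence[float],
    right_vs: Sequence[float],
    curve: ResponseCurve,
) -> float:
    """Full decision pipeline: per-neighbor biases, per-eye weighted
    averages, signed summation across eyes, single clip to [0, 1].

    ``left_vs`` / ``right_vs`` are the vertical occupancies (deg) of the
    neighbors seen by each eye.  The per-eye averages use the age's weight
    rule; averaging is across neighbors since each neighbor's bias is
    constant along the sub-angles it occupies.
    """
    s = 0.5
    for side, vs in (("left", left_vs), ("right", right_vs)):
        vs = list(vs)
        if not vs:
            continue
        w = _weights(vs, curve.age)
        s += sum(wi * curve.bias(v, side) for wi, v in zip(w, vs))
    return min(1.0, max(0.0, s))


@dataclass(frozen=True)
class WallResponse:
    """Probability of turning away from the wall vs. distance (body lengths).

    Piecewise linear from ``p_max`` at the wall down to chance (0.5) at
    ``chance_distance_bl``, constant beyond.  In the simulator the curve is
    consulted only below ``engage_distance_bl``, inside which neighbors are
    ignored entirely.
    """

    p_max: float = 0.8
    chance_distance_bl: float = 3.0
    engage_distance_bl: float = 2.0

    def __post_init__(self):
        if not 0.5 <= self.p_max <= 1.0:
            raise ValueError("WallResponse.p_max must lie in [0.5, 1]")
        if self.chance_distance_bl <= 0:
            raise ValueError("WallResponse.chance_distance_bl must be positive")

    def __call__(self, distance_bl: float) -> float:
        if distance_bl < 0:
            raise ValueError("distance to the wall must be non-negative")
        if distance_bl >= self.chance_distance_bl:
            return 0.5
        frac = distance_bl / self.chance_distance_bl
        return self.p_max + (0.5 - self.p_max) * frac


def wall_turn_probability(
    distance_bl: float, wall: WallResponse | None = None
) -> float:
    """p(turn away from the wall) at ``distance_bl`` body lengths."""
    return (wall or WallResponse())(distance_bl)


@dataclass(frozen=True)
class GroupDeltaCurve:
    """Turn probability vs. inter-eye occupancy difference, as inferred from
    group-swimming trajectories (rather than closed-loop single-fish assays).

    Odd about ``delta = 0``.  ``style='monotone'`` (7 dpf): fish turn away
    from the more occupied side, saturating at ``peak_p`` beyond
    ``peak_delta_deg``.  ``style='peaked'`` (14/21 dpf): fish turn towards
    the more occupied side with maximal tendency at intermediate
    ``|delta| = peak_delta_deg`` and a decay back to chance by
    ``return_to_chance_deg``.

    ``delta`` is negative when the left eye is more occupied.
    """

    age: int
    style: str = ""
    peak_delta_deg: float = 30.0
    peak_p: float = 0.65
    return_to_chance_deg: float = 90.0

    def __post_init__(self):
        style = self.style or ("monotone" if self.age == 7 else "peaked")
        if style not in ("monotone", "peaked"):
            raise ValueError(f"unknown GroupDeltaCurve style {style!r}")
        if not 0.5 <= self.peak_p <= 1.0:
            raise ValueError("GroupDeltaCurve.peak_p must lie in [0.5, 1]")
        object.__setattr__(self, "style", style)
        d, p = self.peak_delta_deg, self.peak_p
        if style == "monotone":
            # away from the more occupied side: more left (delta<0) -> right
            xs = [-d, 0.0, d]
            ps = [p, 0.5, 1.0 - p]
        else:
            # towards the more occupied side, fading at large |delta|
            r = self.return_to_chance_deg
            xs = [-r, -d, 0.0, d, r]
            ps = [0.5, 1.0 - p, 0.5, p, 0.5]
        object.__setattr__(self, "_xs", xs)
        object.__setattr__(self, "_ps", ps)

    def __call__(self, delta: float) -> float:
        if np.ndim(delta) == 0:
            return _interp_hold(float(delta), self._xs, self._ps)
        return np.interp(np.asarray(delta, dtype=float), self._xs, self._ps)


def group_derived_turn_probability(
    delta_deg: float, age: int, curve: GroupDeltaCurve | None = None
) -> float:
    """p(turn right | inter-eye occupancy difference ``delta_deg``)."""
    return (curve or GroupDeltaCurve(age=age))(delta_deg)


def default_response_curve(age: int) -> ResponseCurve:
    """Packaged default curve for an age (7, 14 or 21 dpf)."""
    if age not in DEFAULT_VR_ANCHORS:
        raise ValueError(f"no default response curve for age {age}")
    return ResponseCurve(age=age, anchors=tuple(DEFAULT_VR_ANCHORS[age]))
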