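# Methods

This note documents the model implemented by `shoalsim`, the choices made
where the underlying behavioral literature leaves the design open, and what
the test suite does and does not establish.

## Units and conventions

Positions in cm, time in seconds, angles in degrees at every file and API
boundary (headings in trajectory arrays are radians, counter-clockwise
positive, x east / y north).  Logged turn angles are positive for rightward
(clockwise) turns.  Response curves are stored in the left-stimulus frame:
`p` is the probability of turning right given the stimulus on the left eye,
so `p > 0.5` is repulsion.  The inter-eye occupancy difference Δ is
negative when the left eye is more occupied.

## Retinal geometry

Each eye's field spans 165° from the direction of motion backwards, leaving
a 30° blind zone behind the fish; a point dead ahead tie-breaks to the
right eye (arbitrary, deterministic, measure zero).  Ray casting uses 1000
rays per eye (0.165°/ray); a neighbor's body is a rectangle of length
|head − tail| and configured width, and a ray hits iff its bearing falls in
the interval spanned by the corner bearings (exact for a convex body seen
from outside; the tests check this against an explicit 100 000-ray
ray–edge-intersection oracle).  Eye totals are the measure of the union of
hit rays, so overlapping neighbors are not double-counted; per-neighbor
extents may overlap.  Occlusion between neighbors is deliberately not
modelled.

Vertical occupancy is `2·arctan(H/d)` with the *full* body height H in the
arctangent argument, implementing the printed convention literally even
though a vertically centered object of height H subtends `2·arctan(H/2d)`;
distances are centroid-to-centroid (the 0.6 mm eye offset is negligible at
cm scales).

The pinhole retina (eye separation 1.2 mm, radius 0.45 mm, eye height 5 mm
above the floor, effective field 163°, vergence 36°) places the pinhole at
the eye-sphere center with optical axes rotated outward from the heading by
90° − vergence/2 = 72°.  With that placement the image position about the
back-of-retina center equals the direction to the source about the optical
axis, so retinal coordinates are reported as object-side azimuth/elevation;
points behind the pinhole plane fall outside the effective field and are
flagged rather than raised.

## Response functions

Only qualitative constraints on the turn-probability curves are published;
the packaged curves are piecewise-linear interpolants through anchor points
that honor every constraint, with constant extrapolation beyond the last
anchor.  All anchors live in the config file and can be replaced without
code changes:

| age | anchors (v°, p) | constraints honored |
|-----|-----------------|---------------------|
| 7 dpf | (0, .5) (6, .5) (60, .75) | chance below 6°, monotone repulsion beyond |
| 14 dpf | (0, .5) (6, .4) (11, .5) (60, .75) | attraction dip, crossing exactly at 11° |
| 21 dpf | (0, .5) (25, .35) (52, .5) (90, .7) | attraction through 45°, crossing at 52° |

The wall response decays linearly from p_max = 0.8 at the wall to chance at
3 body lengths (p_max is unpublished; configurable).  The group-derived
Δ-curves are odd about Δ = 0: monotone saturation at 7 dpf (turn away from
the more occupied side, peak probability 0.65 beyond 30°), and a peaked,
fading form at 14/21 dpf (turn towards the more occupied side, maximal at
|Δ| = 30°, back to chance by 90°).

Combination rules: within an eye, biases are averaged with size-proportional
weights at 7 dpf and equal weights at 14/21 dpf; across eyes the signed
per-eye averages add, and the result is clipped to [0, 1] once, after the
binocular sum.  Because each neighbor's bias is constant along the
sub-angles it occupies, averaging across neighbors is equivalent to
averaging across visual sub-angles and is what the simulator computes.

## Simulator

Agents live in a circular arena (6.5/9.2/12.6 cm at 7/14/21 dpf) with
age-specific body length (0.4/0.5/0.8 cm), height (0.2/0.25/0.4 cm), bout
rate (1.65/1.4/1.4 Hz), bout displacement (0.1/0.12/0.16 cm), a 320 ms bout
duration, a 20 ms time step, 600 s runs, 5 agents and 50 repetitions by
default, starting uniformly within 0.9 of the arena diameter.

While stationary, an agent starts a bout with per-step hazard
`Δt / (1/rate − bout_duration + Δt)`; the correction for the refractory
bout duration makes the *realized* bout rate equal the configured rate
(a plain `rate·Δt` hazard would produce ~1.08 Hz at 7 dpf).  At onset the
turn direction is drawn from the wall rule (below 2 body lengths from the
wall, neighbors ignored) or the social rule, then the magnitude is drawn
from a half-normal with σ = 30° independent of direction — the published
finding is that vision modulates the probability of directed turns, not
their size; the true magnitude distribution is unpublished and σ is
configurable.  The bout displaces the agent along the new heading over 16
steps with a triangular speed profile (a stand-in for the unpublished
empirical bout profile; its only analytic role is to give the speed trace
clean minima for segmentation), truncated at the arena boundary by clipping
the position to the circle along the motion direction with the heading
unchanged.

A consequence of literal truncation: an agent clipped exactly onto the
boundary whose next bout points outward executes a zero-displacement
"ghost" bout (~2% of bouts at 7 dpf).  These exist in the event log but are
invisible to any observer of the speed trace, so the segmentation-based
bout rate (~1.62 Hz at 7 dpf) sits slightly below the generative rate
(1.65 Hz).

All randomness flows from one seeded generator per run with a fixed draw
order (initial conditions, then per step by agent index: initiation,
direction, magnitude), so runs are bit-reproducible and a social variant
with a flat response curve reproduces the non-social variant exactly under
the same seed.

## Group statistics

Kinematics use symmetric differences over ±1 frame; bouts are the motion
between consecutive interior local minima of the speed trace (flat minima
count once), with per-bout onset refined to the first moving frame.
Nearest-neighbor dispersion is `log(NN1 / NN1_shuffled)` with the natural
logarithm (configurable base).  The shuffled baseline assembles 1000
pseudo-groups, each taking identity i from a distinct, randomly chosen
repetition, at matched time points, and averages their NN1.  The per-group
scalar is `log(time-mean NN1 / baseline)`: with the time average inside the
logarithm a non-interacting group scores zero in expectation, which is the
defining semantics of the measure; averaging the log-ratio over time
instead would carry a negative Jensen offset (≈ −0.05 here) even at
chance.  The time-resolved log-ratio series remains available.

Binned turn responses use 5° bins (1 body length for the wall covariate),
Clopper–Pearson 95% intervals (exact coverage at small counts), and discard
events within 3 body lengths of the wall for occupancy covariates; empty
bins are flagged, not dropped.  The bout-rate variant conditions on the
fish being stationary, so its level is the decision hazard (~3.3 Hz at
7 dpf), above the realized bouts-per-second.

## What the synthetic world does and does not establish

The simulator *is* the object of study here — there is no external data
path.  Its agents reproduce the bout statistics, wall interactions and
visual decision rule described above, but not: body-shaped collisions or
hydrodynamics, alignment-generating mechanisms (simulated groups do not
polarize the way real 14–21 dpf groups do), bout-rate modulation by total
occupancy (held constant by design), occlusions, or 3-D swimming.  A green
dispersion test therefore establishes that the decision rule produces the
measured group structure under these idealizations, not that the rule is
uniquely responsible for it in real fish.

## Known limitations

The exact numerical response curves are published only as figures; the
packaged anchors are constrained stand-ins.  With them, the 7 dpf and
non-social dispersion levels match the reference measurements within their
SDs, but 14 dpf aggregation is statistically indistinguishable from zero
(reference −0.097 ± 0.083) and 21 dpf saturates near −0.2 (reference
−0.55 ± 0.24): the stand-in attraction is too shallow.  Deeper attraction
dips — plausibly present in the unpublished curves — reproduce stronger
shoaling and can be supplied through the config file; the packaged defaults
are deliberately left at the constraint-derived values rather than fitted
to the group-level outcome.  One acceptance-level test
(`test_dispersion_within_reference_sd[21]`) fails for this reason and is
expected to.
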