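# Methods

This note documents the model, its parameters, the synthetic-data
generators and the numerical conventions behind `vnsim`, and what the
tests do and do not establish about real tissue and real trainees.

## Coordinate frame and geometry

All geometry lives in a local **skin frame**: right-handed, millimetres,
origin at the intended umbilical insertion site, x–y the skin tangent
plane, +z the outward normal. Insertion **depth** is penetration measured
along −z; the wall layers are slabs `depth_start ≤ d < depth_end` in that
normal depth. (The distance travelled along the needle shaft is
`depth / sin(insertion angle)`; the normal depth is the quantity every
layer lookup and membrane computation needs, so it is the one stored.)
The stack must be contiguous from depth 0; `layer_at(d)` is a partition:
every depth inside the wall belongs to exactly one layer.

Patient positioning, skin pinching/clamping and the incision are tracked
as a forward-only `scene_state` enum. They gate the "preliminary steps
completed" flag in scoring and deliberately have no geometric effect: the
simulation frame is always the local skin frame, so a statement about the
patient being tilted or prone changes bookkeeping, not physics.

## Tissue parameters

Each layer carries five dimensionless parameters in [0, 1] — stiffness,
damping, static friction, dynamic friction, pop-through — following the
convention of haptic-rendering toolkits where material response is tuned
as unitless knobs. The built-in defaults are the expert-tuned values for
seven tissue models (bowel, linea alba, pancreas, peritoneum, skin,
subcutaneous fat, vasculature); the published table prints a single
friction column, so that one value populates both the static and dynamic
fields (each overridable in config). The subcutaneous-fat row is all
zeros: fat is haptically transparent.

`HapticConfig` maps the knobs to physical units. Defaults:

| scale | default | meaning |
|---|---|---|
| `f_max` | 3.3 N | device force scale; a pop-through of 1.0 yields at the nominal maximum continuous force of the 3-DoF stylus class |
| `stiffness_scale` | 1.0 N/mm | membrane spring rate per unit stiffness |
| `damping_scale` | 0.01 N·s/mm | bulk damping per unit damping |
| `friction_scale` | 1.0 N | bulk friction per unit friction |
| `k_fulcrum` | 0.5 N/mm | lateral fulcrum spring |

The 0–1 → physical mapping is a declared convention of this package (the
tuned values themselves carry no units); every scale is config-exposed so
the mapping can be re-tuned the way the original parameters were.

## Force model

**Needle axis.** The axis is the normalised vector part (qx, qy, qz) of
the orientation quaternion; when the vector part vanishes (pure-scalar
quaternions) the fallback is the device z-axis rotated by Q. Both
readings of "axis from quaternion" are thereby honoured; the vector-part
convention is primary because the trajectory schema stores the axis
there directly.

**Fulcrum.** `F = k_fulcrum (p′ − p)` with p′ the orthogonal projection
of the device position onto the needle line through the insertion point
r (fixed at the first skin crossing, interpolated on the crossing
segment). The restoring sign is the default since the constraint's
purpose is to permit axial but resist lateral motion; the opposite
(outward) sign is available behind `literal_fulcrum_sign` for fidelity
comparisons. F is orthogonal to the axis by construction, with magnitude
`k · distance(p, line)` — both properties are verified against an
independent least-squares projection oracle.

**Membranes and pops.** A layer with `pop_through > 0` presents a
membrane at its entry surface. The shallowest un-popped membrane the tip
presses on loads a spring `stiffness_scale · stiffness · (d − depth_start)`
resisting insertion; when the load reaches `pop_through · f_max` the
membrane pops: the spring releases to zero, the event is logged, and the
membrane stays open for the rest of the traversal. `pop_through = 0`
means *no membrane* (free traversal) — required so the all-zero fat row
is passable. With the default wall, skin punctures at 0.165 N, linea
alba at 0.066 N and peritoneum at 0.165 N; only the latter two are
flagged `distinct`, reproducing the two clinical pops (skin puncture is
logged as an event but not counted among them).

**Bulk terms.** While the tip occupies a layer's bulk (just above a
loaded membrane, otherwise the layer containing the depth), damping is
`damping_scale · damping · v` opposing the axial velocity v, and dynamic
friction is the constant `friction_scale · dynamic_friction` opposing
the motion direction. Below a velocity deadband of 0.1 mm/s friction is
in the static regime: in a sample-driven replay there is no commanded
force to oppose, so the static bound acts as an onset threshold and the
rendered force is zero. Depth deeper layers feel more resistive purely
through their table values; no hidden depth ramp is added.

**Replay.** `simulate_trajectory` is sample-driven (any rate the
trajectory provides; no fixed servo-loop rate is assumed), vectorises the
per-sample geometry and decomposes `f_total = f_fulcrum + f_spring +
f_damping + f_friction` (an exact vector identity, asserted in tests).
With damping, friction and pops disabled the axial spring is a function
of depth only, hence conservative: net work over a closed depth cycle
vanishes to integration tolerance (< 1e-6 N·mm in the test).

**Contacts.** Organ contact is tested at the tip against analytic sphere
sets (deformable organs are *represented by* their filling spheres) or
triangle meshes via the in-package ray-crossing test accelerated by the
AABB tree. Contiguous penetration of one organ debounces to a single
contact event; re-entry after full exit counts again.

## Collision primitives

The AABB tree is a median-split tree over triangle bounding boxes; its
queries return a superset of the triangles within reach and are verified
to be *exactly* the brute-force set for box/segment queries on the test
meshes. Closest-point queries use Ericson's per-triangle closest-point
routine over tree-culled candidates. Point-in-mesh is ray-crossing
parity with a fixed irrational ray direction to avoid axis-aligned edge
grazing. `fill_spheres` rejection-samples interior points, picks centers
by farthest-point selection (first center at the centroid when interior),
and assigns each the center-to-surface distance as radius, so every
sphere lies fully inside the closed mesh; open meshes are rejected toward
rigid contact.

## Synthetic anatomy

The published simulator used CT-derived patient meshes that are not
redistributable; `generate_anatomy` builds a configurable stand-in. The
default wall is skin 3 mm, subcutaneous fat 20 mm, linea alba 2 mm,
peritoneum 1 mm (26 mm total) — representative adult peri-umbilical
values, chosen once as the package default and fully overridable since
the source thicknesses are not published. Forbidden organs are analytic
sphere sets: bowel loops placed along the nominal 45° insertion line
roughly 16 mm past the wall (so a drive well past the peritoneum strikes
them, while a correctly stopped insertion stays > 3 mm clear across the
40–55° range the generator produces), colon laterally, pancreas and the
great-vessel chain retroperitoneally deep, and "lateral peritoneum"
spheres flanking the corridor at wall depth — the latter modelled as
geometry distinct from the peritoneum wall layer, which must of course
be traversed and is never a mistake. Placement jitter is deterministic
per seed, and a corridor-clearance check rejects any forbidden organ
intruding into the insertion corridor above the wall bottom.

## Synthetic trainees

`generate_attempt` produces straight-line insertions: orient once (angle
drawn from Normal(45 + bias, sd) degrees, azimuth fixed), then advance at
constant axial speed with additive lateral tremor; no mid-insertion
re-orientation, matching the orient-then-push protocol and keeping the
angle metrics analytic. Events are always emitted in protocol order
(step1–3, timer_start, …, freeze, timer_stop). Attempt B multiplies
bias, sd and duration by `learning_gain ∈ (0, 1]`. Overshoot (probability
per profile) drives 18 mm past the wall into the bowel loops before
retracting to the nominal 3 mm cavity depth. Randomness flows through
named streams seeded by (seed, subject, attempt), so cohorts extend
without reshuffling existing subjects.

Cohort defaults mirror a 14-participant, two-group, two-platform pilot:
half "experienced" (tighter angle spread, faster, overshoot 0.1, learning
gain 0.85), half "student" (wider spread, slower, overshoot 0.25, gain
0.75), platforms alternating within group. These are declared
conventions — the generator emulates plausible motor behaviour and a
within-session learning effect, not fitted human kinematics. Passing
tests therefore demonstrate that the pipeline *measures what the
generator injects* (calibrated type-I error, recovered learning effects),
not that real trainees behave this way; no biomechanical tremor spectrum,
re-aiming, or device-specific jitter is modelled.

## Scoring

Insertion angle is the angle between the needle axis and the skin
tangent plane, evaluated at the **freeze** event (the protocol's
self-assessment instant; final sample as a warned fallback). The ±5°
tolerance is inclusive at the boundary. Wrong orientation counts at most
once per attempt (one attempt = one insertion); total mistakes =
forbidden contacts + wrong orientation, an identity asserted everywhere.
Duration requires both timer events and is their difference.

## Statistics

The signed-rank test drops zero differences before ranking (classic
treatment; Pratt's zero-rank method is an option), assigns mid-ranks to
tied absolute differences, and computes the two-tailed p exactly by full
enumeration of all 2ⁿ sign assignments for n ≤ 12 effective pairs
(≤ 4096 terms), above that a normal approximation with the tie-corrected
variance Var(W⁺) = Σrᵢ²/4 and a 0.5 continuity correction. The exact
branch equals an independent itertools enumeration oracle on randomized
fixtures for every n ≤ 12, and matches scipy's exact mode in the
untied case. At the pilot's n = 14 the approximation's measured size at
α = 0.1 is ≈ 0.09–0.11 over 1000 replicate null studies — the calibration
the acceptance script re-measures. Tests at n_eff < 5 are flagged
underpowered (no exact two-tailed p can fall below 0.1 there).

Quartiles use linear interpolation between order statistics (the common
spreadsheet/statistical default); the method string is config-selectable
and descriptives are permutation-invariant and affine-equivariant. SUS
scoring follows the standard instrument: Σ[(odd item − 1) + (5 − even
item)] × 2.5, bounds 0 and 100 attained exactly at the extreme responses.

`cohort_report` excludes (and lists) unpaired subjects, reports
median (Q1–Q3) for attempts A and B, the per-subject improvement deltas
A − B, and the paired test per performance index, grouped by
group × platform, by platform only (expertise-independent pooling), or
as one cell.

## Problem sizes and determinism

The default test and acceptance runs use cohorts of 14–50 subjects,
trajectories of ~30–90 samples, 10⁴ random poses for the fulcrum oracle,
100 segment queries per mesh for the BVH check, and 1000 replicate null
studies for the type-I calibration — sizes chosen so the whole suite
replays in well under a minute of simulation time while keeping binomial
standard errors small enough for 3-SE acceptance bands. Every random
draw descends from an explicit integer seed; the full pipeline is
bitwise reproducible for a fixed (config, seed), and every written
artifact embeds the seed and a config hash.

## Known limitations

- No deformable FEM: deformables are the sphere-fill contact
  approximation only; no tissue displacement or respiration motion.
- The needle is a point at the tip for contact purposes; shaft–organ
  contact is not tested.
- The 0–1 → Newton mapping is a convention, not a biomechanical
  identification; absolute force magnitudes should be read comparatively.
- The trainee generator's noise model is declared, not inferred from
  human recordings; statistical power numbers transfer to real studies
  only insofar as real effect sizes resemble the generator's.
- Static friction renders zero force at rest (onset-threshold reading);
  a servo-loop implementation against a commanded force would differ.
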