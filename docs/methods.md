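# Methods

## The kinematic model

`cgmsens.cgm` implements the left lower limb of the Conventional Gait Model
in its classic hierarchical, top-down form:

* **Pelvis** — origin at the mid-ASIS point; lateral axis along RASI→LASI;
  anterior axis in the plane of LASI, RASI and SACR (SACR may be supplied
  directly or computed as the PSIS midpoint), orthogonal to the lateral
  axis; vertical axis completes the right-handed triad.
* **Hip joint centre** — Newington/Davis regression in the pelvis frame:
  with leg length `LL` and inter-ASIS distance `A` (mm),
  `C = 0.115·LL − 15.3`, `troc = 0.1288·LL − 48.56`, θ = 0.5 rad,
  β = 0.314 rad, marker radius `mm`:
  `x = C·cosθ·sinβ − (troc+mm)·cosβ`, `y = A/2 − C·sinθ` (left),
  `z = −C·cosθ·cosβ − (troc+mm)·sinβ`.
* **Knee/ankle joint centres** — chord construction: the joint centre J
  lies in the plane of the proximal centre P, the lateral marker M and the
  wand W, with `|J−M| = width/2 + marker radius` and a right angle at J.
  The closed form is `J = M + r·((r/d)·u − sqrt(1−(r/d)²)·v)` with
  `d = |P−M|`, `u = (P−M)/d` and `v` the in-plane unit vector toward the
  wand; the minus sign places J opposite the wand, which is where the true
  joint centre sits when the lateral marker lies on the flexion axis and
  the wand stands off laterally (verified by the generator round-trip and
  an independent root-finding oracle in the tests).
* **Segment triads** — femur/tibia: long axis from the distal joint centre
  to the proximal one, flexion axis from the distal centre to the lateral
  marker (orthogonal by the chord construction), anterior axis completes.
  Foot: the AJC→LTOE axis with a dorsal axis orthogonalized from the tibia.
* **Angles** — hip, knee and ankle use the mobile y–x′–z″ Cardan sequence
  (flexion first, floating ab/adduction, long-axis rotation last); the
  pelvis uses rotation–obliquity–tilt with the axial rotation outermost so
  tilt and obliquity do not depend on walking direction. Signs (left side):
  flexion/anterior tilt, adduction/left-up obliquity, internal rotation/
  left-forward rotation, and dorsiflexion positive. Foot progression is the
  transverse-plane angle between the foot axis and the direction of
  progression (net horizontal pelvis displacement; lab X for standing
  trials), internal positive.
* **Static calibration** — stores the hip-centre offsets and the standing
  AJC→LTOE direction in the tibia frame. Under the foot-flat assumption the
  sagittal pitch offset is subtracted from dynamic dorsiflexion. The
  transverse offset is *recorded but not subtracted*: a single toe marker
  carries no independent transverse reference, and subtracting it would
  make any misplacement that is consistent between static and dynamic
  trials cancel exactly out of ankle rotation, which contradicts the
  observed transverse-plane sensitivity of the model family. Tibial torsion
  and thigh/shank rotation offsets are fixed at zero (no medial markers or
  alignment devices are modelled).

Gait-cycle normalization resamples each foot-strike-to-foot-strike interval
to 101 points by linear interpolation; cycles are kept separately and
averaged only when a single representative curve is needed (RMSD, GPS).

## The synthetic-data generator

`cgmsens.synthetic` emulates the capture sessions of a paediatric gait
laboratory: one static standing trial (anatomical zero, foot flat) and one
walking trial at 100 Hz, cadence 120 steps/min, for a ~150 cm child.
Joint-angle templates are sums of up to three harmonics per angle with
defaults that qualitatively match normative walking (knee flexion mean
~22°, range ~6–49°; pelvic obliquity ±4°; …). The exact curve shapes do
not drive the sensitivity conclusions — displacement effects are
near-constant angular offsets — so documented defaults suffice.

Markers are attached with the model's own conventions, which is what makes
the displacement experiment controlled: LKNE/LANK sit on the flexion axes
at the chord radius from the joint centres; wands sit at mid-segment height
in the plane containing the proximal centre, distal centre and flexion
axis. The wand stand-off parameter is the perpendicular distance from the
wand marker to the segment's coronal chord line (hip-centre→knee-marker,
knee-centre→ankle-marker): that lever is what converts an
anterior–posterior wand error of magnitude `e` into an axial segment
rotation of `≈ arctan(e / stand-off)`. Stand-offs are drawn uniformly from
60–90 mm (thigh) and 50–70 mm (shank); with a seed, stature-tied lengths
share a common ±5 % scale factor and joint widths vary independently.
`inter_asis` (235 mm) and `pelvis_depth` (170 mm) are marker-centre
distances: skeletal breadth/depth plus ~17 mm of marker stand-off per
sagittal marker. Marker spheres are 14 mm diameter (radius 7 mm), entering
the chord radii as `width/2 + 7`.

What the generator does **not** emulate: soft-tissue artifact, marker
dropout/gaps, pathological gait beyond amplitude/offset changes, the right
limb, and real inter-laboratory marker-placement habits. Passing tests
therefore demonstrate the *geometric* error propagation of the model, not
the full variability of real captures; absolute effect sizes on real
patients depend on each subject's true wand levers and pelvis dimensions.

Optional noise: per-frame isotropic Gaussian jitter and a fixed per-trial
placement offset, both off by default because the displacement simulations
are noise-free by design. Per-cycle variability (used for corridor demos)
adds smoothly blended per-cycle offsets.

The reference population for GPS is built from 20+ jittered copies of the
template (per-angle mean shift SD 2°, amplitude scale SD 8 %) evaluated
through the generator; its per-point mean and SD stand in for a clinical
normative database.

## The displacement simulator

Each of the eight markers takes one of five positions: original, or 10 mm
along ±two axes of its plane of action, expressed in the owning segment's
frame computed from the *undisplaced* trial (pelvis markers: coronal plane,
medial–lateral and proximal–distal; thigh/shank markers: sagittal plane,
anterior–posterior and proximal–distal; toe: transverse plane,
medial–lateral and anterior–posterior). The code→direction table (D0 =
lateral or anterior, D90 = proximal or anterior, …) is a documented
convention; both signs of each axis are enumerated, so aggregate statistics
do not depend on it. The same segment-local offset is applied to the static
and the dynamic trial — misplacement is consistent across a session. The
full grid enumerates 5^8 = 390,625 specs in deterministic lexicographic
order (null spec first); `sample_grid` draws a uniform seeded sample
without replacement that always contains the null spec, making desk-scale
studies of the grid practical (the package evaluates ≈350 specs/s/core;
results stream to CSV and runs are resumable). Parallel execution is
bit-identical to sequential. Specs whose geometry degenerates are logged
and skipped rather than aborting a long run.

## Numerical choices and edge cases

* Chord: requires the proximal–lateral distance to exceed the radius and
  non-collinear inputs; radius 0 returns the lateral marker.
* Ankle angles: closed-form two-angle solve of
  `Ry(−dorsi)·Rz(−rot)·f0 = f_obs`; of the two rotation branches the
  smaller-magnitude one is taken (physiological range).
* Orthonormality of all triads is enforced to <1e-9; category boundaries
  are exact (≤2, ≤5, ≤10); worst-case ties break lexicographically on the
  spec codes; all angle curves are validated finite.
* Determinism: every stochastic step takes a seed; `run_batch` results are
  independent of worker count; output files carry the seed and a
  configuration hash.

## Problem sizes

The test suite and the acceptance script use two-cycle dynamic trials
(201 frames at 100 Hz), cohorts of 10 subjects for single-marker
statistics, and a 20,000-spec seeded sample of the grid for population
statistics — sizes chosen so a complete desk run finishes in minutes while
keeping Monte-Carlo error well below the decision thresholds (the
single-marker quantities are deterministic per subject; cohort means vary
only through anthropometry draws).

## Known limitations

* The pelvic-plane geometry bounds how insensitive pelvic angles can be:
  displacing both ASIS markers proximally while SACR moves distally pitches
  the three-marker plane by `arctan(20 mm / SACR lever)`, ≈6.7° at the
  realistic child lever of 170 mm. Keeping every pelvic RMSD within 5°
  would require a ≥229 mm lever, beyond realistic paediatric (or adult)
  pelvis dimensions, so the package reports worst-case pelvic tilt slightly
  above the acceptability threshold while all other pelvic claims
  (obliquity ≤5°, rotation nearly immune, majority of pelvic outcomes ≤2°)
  hold.
* Only the left limb is modelled; GPS is the nine-variable single-side
  variant (a both-sides GPS would react even more strongly).
* Only one displacement magnitude per run (10 mm default) and four
  directions per marker are simulated.
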