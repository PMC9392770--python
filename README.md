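# cgmsens

Marker-misplacement sensitivity analysis for the Conventional Gait Model
(CGM, the "Plug-in Gait" family of clinical lower-limb models).

## The problem

Clinical gait analysis computes joint-angle curves from reflective markers
placed on bony landmarks, and those curves drive treatment decisions for
patients with motor disorders such as cerebral palsy. Marker placement is
the dominant source of variability: misplacing a marker by millimetres can
shift reported joint rotations by clinically meaningful amounts (2° is
usually considered the optimal reproducibility threshold and 5° the
acceptable one). `cgmsens` quantifies this sensitivity for the eight
markers that define one lower limb (LASI, RASI, SACR, LTHI, LKNE, LTIB,
LANK, LTOE — left side) by *virtual* displacement: every marker may stay
put or move 10 mm in one of four 90°-spaced directions within its plane of
action, giving a combinatorial grid of

    n_sim = s^m = 5^8 = 390,625

displacement combinations. For each combination the static calibration and
dynamic kinematics are recomputed and compared with the undisplaced
kinematics by the root-mean-square deviation over the normalized gait
cycle,

    RMSD_angle = sqrt( (1/101) * sum_t ( theta_sim(t) - theta_orig(t) )^2 ),

binned into four severity categories (≤2°, >2–5°, >5–10°, >10°), and
summarized by the Gait Profile Score

    GVS_v = RMS_t( theta_v(t) - ref_mean_v(t) ),   GPS = RMS_v( GVS_v )

over the nine single-side GPS variables. The package is aimed at gait-lab
scientists and biomechanics researchers who want to study error propagation
through the CGM's hierarchical, top-down segment chain without collecting
patient data.

Because no motion-capture data ship with the package, a forward-kinematic
generator (`cgmsens.synthetic`) produces static and walking trials for
synthetic child subjects with *known* joint angles, using exactly the
segment conventions the model assumes (regression hip centre, chord-function
knee/ankle centres, wand-defined flexion axes). On noise-free trials the
model recovers the generating angles to ~1e-13 degrees, so any deviation
measured under displacement is pure marker geometry, not model error.

## Worked example

```python
from cgmsens import (make_anthropometry, forward_kinematics, run_batch)
from cgmsens.displacement import DisplacementSpec

anthro = make_anthropometry("child")          # ~150 cm child, preset means
static, dynamic, events, truth = forward_kinematics(anthro)

spec = DisplacementSpec.single("LTHI", "D0")  # thigh wand 10 mm anterior
result = run_batch(static, dynamic, events, anthro, [spec])[0]
print(round(result.rmsd_per_angle["hip_rotation"], 2))
print(round(result.rmsd_per_angle["pelvis_tilt"], 2))
```

prints

```
7.56
0.0
```

A single 10 mm anterior misplacement of the femoral wand shifts hip
rotation by 7.6° RMSD — beyond the 5° acceptability limit and close to the
small-angle prediction arctan(10 mm / 75 mm wand stand-off) — while the
pelvis, which sits *above* the wand in the model hierarchy, is untouched.

The `examples/` directory holds five narrative scripts covering trial
generation, the round-trip validation, the single-marker impact table, the
sampled-grid category distributions and GPS/corridor statistics. A thin CLI
mirrors the pipeline for shell use:

```bash
cgmsens generate --preset child --seed 1 --out-dir session/
cgmsens simulate --static session/static.csv --dynamic session/dynamic.csv \
        --anthro session/anthropometry.yml --mode sample --n 20000 --seed 1 \
        --workers 4 --out results.csv
cgmsens report --results results.csv --out-dir report/
```

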