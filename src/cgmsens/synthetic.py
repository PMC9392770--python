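"""Forward-kinematic synthetic gait trials with known ground truth.

Segments are posed from smooth periodic joint-angle templates and markers
are attached using exactly the conventions the kinematic model assumes:
the lateral knee/ankle markers sit on the flexion axes at the chord radius
from the joint centres, and the wands sit in the plane containing the
proximal joint centre, the distal joint centre and the flexion axis, at
their stand-off distance from the segment's coronal chord line.  In
noise-free mode the model therefore recovers the generating angles to
machine precision, which is what makes the displacement simulations a
controlled experiment.

The templates are sums of up to three harmonics per angle whose defaults
qualitatively match normative walking; their exact shape does not drive
the sensitivity conclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .anthropometry import Anthropometry, make_anthropometry
from .cgm import estimate_hjc
from .exceptions import ValidationError
from .geometry import rotation_yxz, rotation_zxy
from .trial import GaitEvents, KinematicCurves, MarkerTrajectorySet

__all__ = [
    "GaitTemplate",
    "default_template",
    "forward_kinematics",
    "make_reference_population",
    "ReferencePopulation",
]

#: Poseable degrees of freedom driven by the template, in degrees.
TEMPLATE_ANGLES = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "ankle_rotation",
)


@dataclass(frozen=True)
class GaitTemplate:
    """Periodic joint-angle curves: mean plus up to three harmonics.

    ``curves[name] = (mean, ((amp1, phase1), (amp2, phase2), ...))`` with
    ``angle(t) = mean + sum_k amp_k * cos(2*pi*k*phase_fraction + phase_k)``
    (degrees; phases in radians).  ``cadence`` is in steps/min, so one gait
    cycle (stride) lasts ``120 / cadence`` seconds.
    """

    curves: dict[str, tuple[float, tuple[tuple[float, float], ...]]]
    cadence: float = 120.0
    n_cycles: int = 4
    cycle_variability_sd: float = 0.0  # degrees, per-cycle offset jitter

    def __post_init__(self) -> None:
        if not self.cadence > 0:
            raise ValidationError("cadence must be positive")
        if self.n_cycles < 1:
            raise ValidationError("need at least one gait cycle")
        if self.cycle_variability_sd < 0:
            raise ValidationError("cycle_variability_sd must be non-negative")
        for name, (mean, harm) in self.curves.items():
            if name not in TEMPLATE_ANGLES:
                raise ValidationError(f"unknown template angle {name!r}")
            vals = [mean] + [v for pair in harm for v in pair]
            if not all(np.isfinite(v) for v in vals):
                raise ValidationError(f"template curve {name!r} has non-finite parameters")
            if len(harm) > 3:
                raise ValidationError("at most three harmonics per angle")

    @property
    def stride_time(self) -> float:
        """Seconds per gait cycle (two steps)."""
        return 120.0 / self.cadence

    def evaluate(self, phase: np.ndarray) -> dict[str, np.ndarray]:
        """Angle values (degrees) at the given cycle fractions."""
        phase = np.asarray(phase, dtype=float)
        out: dict[str, np.ndarray] = {}
        for name in TEMPLATE_ANGLES:
            mean, harm = self.curves.get(name, (0.0, ()))
            y = np.full_like(phase, float(mean))
            for k, (amp, ph) in enumerate(harm, start=1):
                y = y + amp * np.cos(2.0 * np.pi * k * phase + ph)
            out[name] = y
        return out


def default_template(**overrides) -> GaitTemplate:
    """Normative-walking template (healthy child, self-selected speed)."""
    curves = {
        "pelvis_tilt": (10.0, ((1.0, 0.3), (1.5, 0.8))),
        "pelvis_obliquity": (0.0, ((4.0, -1.2),)),
        "pelvis_rotation": (0.0, ((5.0, 0.0),)),
        "hip_flexion": (12.0, ((22.0, 0.35),)),
        "hip_adduction": (2.0, ((5.0, -0.5),)),
        "hip_rotation": (0.0, ((3.0, 1.0),)),
        "knee_flexion": (22.0, ((15.0, 2.4), (12.0, -1.2))),
        "ankle_dorsiflexion": (2.0, ((5.0, 2.0), (5.0, -2.4))),
        "ankle_rotation": (-5.0, ((3.0, 0.5),)),
    }
    params = dict(curves=curves, cadence=120.0, n_cycles=4, cycle_variability_sd=0.0)
    curve_overrides = {k: v for k, v in overrides.items() if k in TEMPLATE_ANGLES}
    params["curves"] = {**curves, **curve_overrides}
    for k, v in overrides.items():
        if k not in TEMPLATE_ANGLES:
            params[k] = v
    return GaitTemplate(**params)


def _smooth_cycle_offsets(
    rng: np.random.Generator, sd: float, n_cycles: int, phase_abs: np.ndarray, n_angles: int
) -> np.ndarray:
    """Per-cycle additive offsets, linearly blended between cycle centres."""
    centres = np.arange(n_cycles) + 0.5
    vals = rng.normal(0.0, sd, size=(n_angles, n_cycles))
    return np.stack(
        [
            np.interp(phase_abs, centres, v, left=v[0], right=v[-1])
            for v in vals
        ]
    )


def forward_kinematics(
    anthro: Anthropometry,
    template: GaitTemplate | None = None,
    rate: float = 100.0,
    seed: int | None = None,
    *,
    n_static_frames: int = 101,
    marker_noise_sd: float = 0.0,
    placement_noise_sd: float = 0.0,
) -> tuple[MarkerTrajectorySet, MarkerTrajectorySet, GaitEvents, KinematicCurves]:
    """Generate a static trial, a dynamic trial, events and truth curves.

    The static trial is the anatomical zero pose with the foot flat; the
    dynamic trial walks along lab +X at the template cadence.  ``truth``
    holds the generating joint angles per dynamic frame, including the
    derived foot-progression angle (knee varus/rotation are structurally
    zero: the generator has no medial knee/ankle information to pose them).

    ``marker_noise_sd`` adds isotropic Gaussian jitter per marker and frame;
    ``placement_noise_sd`` adds a fixed per-trial offset per marker (both
    default off: the displacement simulations are noise-free by design).
    """
    if template is None:
        template = default_template()
    if rate < 50:
        raise ValidationError("rate must be at least 50 Hz")
    rng = np.random.default_rng(seed)

    stride_t = template.stride_time
    n_frames = int(round(template.n_cycles * stride_t * rate)) + 1
    t = np.arange(n_frames) / rate
    phase_abs = t / stride_t
    phase = phase_abs % 1.0

    angles = template.evaluate(phase)
    if template.cycle_variability_sd > 0:
        offs = _smooth_cycle_offsets(
            rng, template.cycle_variability_sd, template.n_cycles, phase_abs,
            len(TEMPLATE_ANGLES),
        )
        angles = {k: angles[k] + offs[i] for i, k in enumerate(TEMPLATE_ANGLES)}

    speed = 1.5 * anthro.leg_length / stride_t  # stride length ~1.5 x leg length
    origin = np.stack(
        [speed * t, np.zeros(n_frames), np.full(n_frames, anthro.leg_length + 80.0)],
        axis=-1,
    )
    static_origin = np.array([0.0, 0.0, anthro.leg_length + 80.0])

    markers, truth = _pose_markers(anthro, angles, origin)

    zero = {k: np.zeros(n_static_frames) for k in TEMPLATE_ANGLES}
    static_markers, _ = _pose_markers(
        anthro, zero, np.broadcast_to(static_origin, (n_static_frames, 3)).copy()
    )

    if placement_noise_sd > 0:
        for mk in markers:
            off = rng.normal(0.0, placement_noise_sd, size=3)
            markers[mk] = markers[mk] + off
            static_markers[mk] = static_markers[mk] + off
    if marker_noise_sd > 0:
        for mk in markers:
            markers[mk] = markers[mk] + rng.normal(0.0, marker_noise_sd, markers[mk].shape)
            static_markers[mk] = static_markers[mk] + rng.normal(
                0.0, marker_noise_sd, static_markers[mk].shape
            )

    labels = tuple(markers)
    dynamic = MarkerTrajectorySet(
        labels, np.stack([markers[k] for k in labels], axis=1), rate
    )
    static = MarkerTrajectorySet(
        labels, np.stack([static_markers[k] for k in labels], axis=1), rate
    )

    strikes = [int(round(k * stride_t * rate)) for k in range(template.n_cycles + 1)]
    strikes[-1] = min(strikes[-1], n_frames - 1)
    offs = [int(round((k + 0.6) * stride_t * rate)) for k in range(template.n_cycles)]
    events = GaitEvents(strikes=tuple(strikes), offs=tuple(offs))

    return static, dynamic, events, KinematicCurves(truth, domain="frames", rate=rate)


def _pose_markers(
    anthro: Anthropometry, angles: dict[str, np.ndarray], origin: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Place the eight left-limb markers for the given angle curves."""
    rad = np.radians

    tilt = rad(angles["pelvis_tilt"])
    obl = rad(angles["pelvis_obliquity"])
    rot = rad(angles["pelvis_rotation"])
    R_p = rotation_zxy(-rot, obl, tilt)

    def local(R, v):
        return np.einsum("fij,j->fi", R, np.asarray(v, float))

    A2 = anthro.inter_asis / 2.0
    markers = {
        "LASI": origin + local(R_p, [0.0, A2, 0.0]),
        "RASI": origin + local(R_p, [0.0, -A2, 0.0]),
        "SACR": origin + local(R_p, [-anthro.pelvis_depth, 0.0, 0.0]),
    }

    hjc = origin + local(R_p, estimate_hjc(anthro))

    R_hip = rotation_yxz(
        -rad(angles["hip_flexion"]), -rad(angles["hip_adduction"]),
        -rad(angles["hip_rotation"]),
    )
    R_f = np.einsum("fij,fjk->fik", R_p, R_hip)
    T = anthro.thigh_length
    kjc = hjc - T * R_f[..., 2]
    rho_k = anthro.knee_chord_radius
    markers["LKNE"] = kjc + rho_k * R_f[..., 1]
    # wand at mid-thigh height, stand-off measured to the HJC-KNE chord line
    d_t = math.hypot(rho_k, T)
    y_wand = rho_k * 0.5 + anthro.thigh_wand_standoff * d_t / T
    markers["LTHI"] = kjc + local(R_f, [0.0, y_wand, 0.5 * T])

    R_knee = rotation_yxz(rad(angles["knee_flexion"]), 0.0, 0.0)
    R_t = np.einsum("fij,fjk->fik", R_f, R_knee)
    S = anthro.shank_length
    ajc = kjc - S * R_t[..., 2]
    rho_a = anthro.ankle_chord_radius
    markers["LANK"] = ajc + rho_a * R_t[..., 1]
    d_s = math.hypot(rho_a, S)
    y_wand_s = rho_a * 0.5 + anthro.shank_wand_standoff * d_s / S
    markers["LTIB"] = ajc + local(R_t, [0.0, y_wand_s, 0.5 * S])

    # foot: standing pitch from the ankle height above the sole
    ankle_height = min(anthro.ankle_width, 0.6 * anthro.foot_length)
    p0 = math.asin(ankle_height / anthro.foot_length)
    f0 = np.array([math.cos(p0), 0.0, -math.sin(p0)])
    R_ankle = rotation_yxz(
        -rad(angles["ankle_dorsiflexion"]), 0.0, -rad(angles["ankle_rotation"])
    )
    f_local = np.einsum("fij,j->fi", R_ankle, f0)
    f_lab = np.einsum("fij,fj->fi", R_t, f_local)
    markers["LTOE"] = ajc + anthro.foot_length * f_lab

    truth = {
        "pelvis_tilt": angles["pelvis_tilt"],
        "pelvis_obliquity": angles["pelvis_obliquity"],
        "pelvis_rotation": angles["pelvis_rotation"],
        "hip_flexion": angles["hip_flexion"],
        "hip_adduction": angles["hip_adduction"],
        "hip_rotation": angles["hip_rotation"],
        "knee_flexion": angles["knee_flexion"],
        "knee_varus": np.zeros_like(angles["knee_flexion"]),
        "knee_rotation": np.zeros_like(angles["knee_flexion"]),
        "ankle_dorsiflexion": angles["ankle_dorsiflexion"],
        "ankle_rotation": angles["ankle_rotation"],
        "foot_progression": -np.degrees(np.arctan2(f_lab[:, 1], f_lab[:, 0])),
    }
    return markers, truth


@dataclass
class ReferencePopulation:
    """Normalized curves of synthetic asymptomatic subjects, with mean/SD."""

    curves: list[KinematicCurves]
    mean: dict[str, np.ndarray]  # angle -> (101,)
    sd: dict[str, np.ndarray]


def make_reference_population(
    n_subjects: int,
    seed: int | None = None,
    template: GaitTemplate | None = None,
) -> ReferencePopulation:
    """Normalized reference curves for a synthetic asymptomatic cohort.

    Each subject gets seeded anthropometry and a jittered copy of the
    template (per-angle mean shift sd 2 deg, amplitude scale sd 8 %); the
    trial is generated by forward kinematics and the truth curves are
    cycle-normalized.  Per-point mean and SD are across subjects.
    """
    if n_subjects < 2:
        raise ValidationError("need at least two subjects (SD undefined otherwise)")
    if template is None:
        template = default_template()
    rng = np.random.default_rng(seed)
    from .cgm import normalize_cycle  # late import to avoid cycle at module load

    curves: list[KinematicCurves] = []
    for _ in range(n_subjects):
        anthro = make_anthropometry("child", seed=rng)
        jittered = {}
        for name, (mean, harm) in template.curves.items():
            scale = rng.lognormal(0.0, 0.08)
            jittered[name] = (
                mean + rng.normal(0.0, 2.0),
                tuple((amp * scale, ph) for amp, ph in harm),
            )
        tpl = replace(template, curves=jittered, n_cycles=1)
        _, _, events, truth = forward_kinematics(
            anthro, tpl, rate=100.0, seed=int(rng.integers(2**31))
        )
        curves.append(normalize_cycle(truth, events))

    stacked = {
        name: np.vstack([c[name] for c in curves])
        for name in curves[0].angles
    }
    mean = {k: v.mean(axis=0) for k, v in stacked.items()}
    sd = {k: v.std(axis=0, ddof=1) for k, v in stacked.items()}
    return ReferencePopulation(curves=curves, mean=mean, sd=sd)
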