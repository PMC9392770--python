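"""Conventional Gait Model lower-limb kinematics (left side).

The model follows the hierarchical top-down conventions of the classic
clinical gait model (Plug-in Gait style): the pelvis is built from the two
anterior-superior-iliac-spine markers and the sacrum marker; the hip joint
centre comes from the Newington/Davis regression in the pelvis frame; knee
and ankle joint centres come from the chord construction using the lateral
marker, the proximal joint centre and the segment wand; the foot is the
ankle-centre-to-toe-marker axis with static pitch/rotation offsets from a
foot-flat standing trial.

Sign conventions (left side): flexion / anterior pelvic tilt positive,
adduction / left-side-up obliquity positive, internal rotation / left-side
forward pelvic rotation positive, dorsiflexion positive, foot progression
positive when the toes point toward the midline.

Medial knee/ankle markers and knee-alignment devices are not modelled:
tibial torsion and thigh/shank rotation offsets are fixed at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anthropometry import Anthropometry
from .exceptions import DegenerateGeometryError, MissingMarkerError, ValidationError
from .geometry import (
    chord_joint_center,
    euler_yxz,
    euler_zxy,
    pelvis_frame,
    relative_rotation,
    segment_frame_from_centres,
    unit,
)
from .trial import ANGLE_NAMES, GaitEvents, KinematicCurves, MarkerTrajectorySet

__all__ = [
    "Calibration",
    "sacrum_virtual_marker",
    "estimate_hjc",
    "static_calibration",
    "segment_frames",
    "compute_kinematics",
    "normalize_cycle",
]

# Newington/Davis hip-joint-centre regression constants, as used by the
# classic clinical gait model implementations (Davis et al. 1991; Vicon
# Plug-in Gait and its open-source clones).  Lengths in mm, angles in rad.
_HJC_THETA = 0.5
_HJC_BETA = 0.314


def sacrum_virtual_marker(trial: MarkerTrajectorySet) -> MarkerTrajectorySet:
    """Ensure a SACR marker, computing the PSIS midpoint when needed."""
    if "SACR" in trial:
        return trial
    if "LPSI" in trial and "RPSI" in trial:
        return trial.with_marker("SACR", 0.5 * (trial["LPSI"] + trial["RPSI"]))
    raise MissingMarkerError("SACR (or LPSI+RPSI)")


def estimate_hjc(anthro: Anthropometry, side: str = "left") -> np.ndarray:
    """Hip-joint-centre offset from the mid-ASIS origin, in the pelvis frame.

    Regression on leg length and inter-ASIS distance; the returned offset is
    posterior (x < 0), distal (z < 0) and lateral to the midline (y > 0 for
    the left side).
    """
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    L = anthro.leg_length
    C = 0.115 * L - 15.3
    aa = anthro.inter_asis / 2.0
    troc = 0.1288 * L - 48.56
    mm = anthro.marker_radius
    x = C * math.cos(_HJC_THETA) * math.sin(_HJC_BETA) - (troc + mm) * math.cos(_HJC_BETA)
    y = aa - C * math.sin(_HJC_THETA)
    z = -C * math.cos(_HJC_THETA) * math.cos(_HJC_BETA) - (troc + mm) * math.sin(_HJC_BETA)
    if side == "right":
        y = -y
    return np.array([x, y, z])


@dataclass(frozen=True)
class Calibration:
    """Subject calibration from a static standing trial.

    ``foot_axis_tibia`` is the standing ankle-to-toe direction expressed in
    the tibia frame; the scalar pitch/rotation offsets are derived views of
    the same information (pitch positive toe-down, rotation positive toes
    toward the midline).  Only the pitch offset is subtracted from the
    dynamic angles (the foot-flat assumption constrains the sagittal plane);
    the transverse offset is recorded for diagnostics but ankle rotation is
    measured against the tibia's own anterior axis, since a single toe
    marker carries no calibratable transverse reference.
    """

    hjc_offset: np.ndarray  # (3,) in the pelvis frame, mm
    foot_axis_tibia: np.ndarray  # (3,) unit vector
    foot_pitch_offset: float  # degrees
    foot_rotation_offset: float  # degrees
    anthropometry: Anthropometry


def _chain(trial: MarkerTrajectorySet, anthro: Anthropometry, hjc_offset: np.ndarray):
    """Per-frame joint centres and segment frames for pelvis/femur/tibia/foot."""
    trial.require("LASI", "RASI", "SACR", "LTHI", "LKNE", "LTIB", "LANK", "LTOE")
    origin, R_pelvis = pelvis_frame(trial["LASI"], trial["RASI"], trial["SACR"])
    hjc = origin + np.einsum("fij,j->fi", R_pelvis, hjc_offset)
    kjc = chord_joint_center(hjc, trial["LKNE"], trial["LTHI"], anthro.knee_chord_radius)
    R_femur = segment_frame_from_centres(kjc, hjc, trial["LKNE"])
    ajc = chord_joint_center(kjc, trial["LANK"], trial["LTIB"], anthro.ankle_chord_radius)
    R_tibia = segment_frame_from_centres(ajc, kjc, trial["LANK"])
    foot_axis = unit(trial["LTOE"] - ajc, name="foot axis")
    # foot triad: x along the foot, z dorsal (tibia long axis made orthogonal)
    tz = R_tibia[..., 2]
    z_f = unit(
        tz - np.sum(tz * foot_axis, axis=-1, keepdims=True) * foot_axis,
        name="foot dorsal axis",
    )
    R_foot = np.stack([foot_axis, np.cross(z_f, foot_axis), z_f], axis=-1)
    return {
        "pelvis_origin": origin,
        "R_pelvis": R_pelvis,
        "hjc": hjc,
        "kjc": kjc,
        "R_femur": R_femur,
        "ajc": ajc,
        "R_tibia": R_tibia,
        "foot_axis": foot_axis,
        "R_foot": R_foot,
    }


def segment_frames(trial: MarkerTrajectorySet, calibration: Calibration) -> dict:
    """Per-frame origins and right-handed orthonormal triads per segment."""
    return _chain(trial, calibration.anthropometry, calibration.hjc_offset)


def static_calibration(static: MarkerTrajectorySet, anthro: Anthropometry) -> Calibration:
    """Calibrate a subject from a static standing trial (foot-flat pose).

    The hip-centre regression offsets are stored together with the standing
    foot direction in the tibia frame, averaged over static frames; during
    dynamic trials ankle angles are measured relative to this reference.
    """
    static = sacrum_virtual_marker(static)
    hjc_offset = estimate_hjc(anthro)
    chain = _chain(static, anthro, hjc_offset)
    f_t = np.einsum("fji,fj->fi", chain["R_tibia"], chain["foot_axis"])
    f0 = unit(f_t.mean(axis=0), name="static foot axis")
    pitch = math.degrees(math.asin(float(np.clip(-f0[2], -1.0, 1.0))))
    rotation = math.degrees(math.atan2(-f0[1], f0[0]))
    return Calibration(
        hjc_offset=hjc_offset,
        foot_axis_tibia=f0,
        foot_pitch_offset=pitch,
        foot_rotation_offset=rotation,
        anthropometry=anthro,
    )


def _ankle_angles(f_t: np.ndarray, f0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve dorsiflexion/rotation from the foot axis in the tibia frame.

    Finds the angles (radians) such that ``Ry(-dorsi) @ Rz(-rot) @ f0``
    equals the observed per-frame direction ``f_t``, where ``f0`` is the
    pitch-only reference direction from the static calibration; of the two
    rotation branches the one of smaller magnitude is taken (physiological
    range).
    """
    a, b, c = f0
    fy = f_t[..., 1]
    H = math.hypot(a, b)
    if H < 1e-9:
        raise DegenerateGeometryError("static foot axis is vertical; ankle undefined")
    phi0 = math.atan2(a, b)
    acos_arg = np.arccos(np.clip(fy / H, -1.0, 1.0))
    cand = np.stack([acos_arg - phi0, -acos_arg - phi0], axis=-1)
    cand = (cand + np.pi) % (2 * np.pi) - np.pi
    rot = np.take_along_axis(
        cand, np.argmin(np.abs(cand), axis=-1)[..., None], axis=-1
    )[..., 0]
    q = a * np.cos(rot) + b * np.sin(rot)
    fx, fz = f_t[..., 0], f_t[..., 2]
    dorsi = np.arctan2(q * fz - c * fx, q * fx + c * fz)
    return dorsi, rot


def compute_kinematics(
    trial: MarkerTrajectorySet, calibration: Calibration
) -> KinematicCurves:
    """Frame-by-frame joint angles (degrees) for the reported left-side set.

    Pelvis angles are pelvis-versus-laboratory; hip = femur vs pelvis,
    knee = tibia vs femur, ankle = foot vs tibia (relative to the static
    reference); foot progression is the transverse-plane angle between the
    foot axis and the direction of progression (the horizontal displacement
    of the pelvis origin over the trial, or lab X for a standing trial).
    """
    trial = sacrum_virtual_marker(trial)
    ch = _chain(trial, calibration.anthropometry, calibration.hjc_offset)
    deg = np.degrees

    # pelvis: axial rotation outermost (tilt/obliquity independent of heading)
    c, b, a = euler_zxy(ch["R_pelvis"])
    curves = {
        "pelvis_tilt": deg(a),
        "pelvis_obliquity": deg(b),
        "pelvis_rotation": deg(-c),
    }

    a, b, c = euler_yxz(relative_rotation(ch["R_pelvis"], ch["R_femur"]))
    curves["hip_flexion"] = deg(-a)
    curves["hip_adduction"] = deg(-b)
    curves["hip_rotation"] = deg(-c)

    a, b, c = euler_yxz(relative_rotation(ch["R_femur"], ch["R_tibia"]))
    curves["knee_flexion"] = deg(a)
    curves["knee_varus"] = deg(-b)
    curves["knee_rotation"] = deg(-c)

    f_t = np.einsum("fji,fj->fi", ch["R_tibia"], ch["foot_axis"])
    p0 = math.radians(calibration.foot_pitch_offset)
    f_ref = np.array([math.cos(p0), 0.0, -math.sin(p0)])
    dorsi, rot = _ankle_angles(f_t, f_ref)
    curves["ankle_dorsiflexion"] = deg(dorsi)
    curves["ankle_rotation"] = deg(rot)

    # direction of progression: net horizontal pelvis displacement
    disp = ch["pelvis_origin"][-1] - ch["pelvis_origin"][0]
    disp[2] = 0.0
    if np.linalg.norm(disp) < 1.0:  # standing trial: fall back to lab X
        heading = 0.0
    else:
        heading = math.atan2(disp[1], disp[0])
    az = np.arctan2(ch["foot_axis"][:, 1], ch["foot_axis"][:, 0])
    fp = -(az - heading)
    curves["foot_progression"] = deg((fp + np.pi) % (2 * np.pi) - np.pi)

    return KinematicCurves({k: curves[k] for k in ANGLE_NAMES}, domain="frames",
                           rate=trial.rate)


def normalize_cycle(curves: KinematicCurves, events: GaitEvents) -> KinematicCurves:
    """Resample each foot-strike-to-foot-strike interval to 101 points.

    Linear interpolation on the frame axis; cycles are kept separately
    (output arrays have shape ``(n_cycles, 101)``).
    """
    if curves.domain != "frames":
        raise ValidationError("normalize_cycle expects raw per-frame curves")
    n_frames = len(next(iter(curves.data.values())))
    strikes = [s for s in events.strikes if 0 <= s <= n_frames - 1]
    if len(strikes) < 2:
        raise ValidationError("no complete gait cycle inside the trial")
    frames = np.arange(n_frames, dtype=float)
    out: dict[str, np.ndarray] = {}
    for name, y in curves.data.items():
        cycles = [
            np.interp(np.linspace(s0, s1, 101), frames, y)
            for s0, s1 in zip(strikes, strikes[1:])
        ]
        out[name] = np.vstack(cycles)
    return KinematicCurves(out, domain="cycle")
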