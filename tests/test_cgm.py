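import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgmsens import (
    ANGLE_NAMES,
    GaitEvents,
    KinematicCurves,
    MarkerTrajectorySet,
    compute_kinematics,
    estimate_hjc,
    make_anthropometry,
    normalize_cycle,
    sacrum_virtual_marker,
    static_calibration,
)
from cgmsens.cgm import segment_frames
from cgmsens.exceptions import MissingMarkerError, ValidationError


def _trial(markers: dict, rate=100.0):
    labels = tuple(markers)
    pos = np.stack([np.atleast_2d(markers[k]) for k in labels], axis=1)
    return MarkerTrajectorySet(labels, pos, rate)


# ---------------------------------------------------------------- sacrum

def test_sacrum_is_psis_midpoint_per_frame():
    rng = np.random.default_rng(7)
    lpsi, rpsi = rng.normal(0, 100, (5, 3)), rng.normal(0, 100, (5, 3))
    trial = MarkerTrajectorySet(("LPSI", "RPSI"), np.stack([lpsi, rpsi], axis=1), 100.0)
    out = sacrum_virtual_marker(trial)
    assert np.allclose(out["SACR"], 0.5 * (lpsi + rpsi))


def test_sacrum_passthrough_and_missing():
    trial = _trial({"SACR": [0.0, 0, 0]})
    assert sacrum_virtual_marker(trial) is trial
    with pytest.raises(MissingMarkerError):
        sacrum_virtual_marker(_trial({"LASI": [0.0, 0, 0]}))


# ---------------------------------------------------------------- HJC

def test_hjc_regression_matches_hand_evaluation():
    """Frozen independent evaluation of the regression for the child preset."""
    a = make_anthropometry("child")  # leg 770, inter-ASIS 235, marker radius 7
    assert estimate_hjc(a, "left") == pytest.approx(
        [-34.944129, 82.382079, -78.935451], abs=1e-5
    )


def test_hjc_is_posterior_distal_lateral_and_scales_with_leg_length():
    a = make_anthropometry("child")
    off = estimate_hjc(a, "left")
    assert off[0] < 0 and off[2] < 0 and off[1] > 0
    bigger = make_anthropometry(
        "custom",
        overrides={"leg_length": a.leg_length * 1.3, "thigh_length": a.thigh_length * 1.3,
                   "shank_length": a.shank_length * 1.3},
    )
    assert np.linalg.norm(estimate_hjc(bigger)) > np.linalg.norm(off)
    right = estimate_hjc(a, "right")
    assert right[1] == pytest.approx(-off[1])
    assert right[0] == pytest.approx(off[0]) and right[2] == pytest.approx(off[2])


# ---------------------------------------------------------------- calibration

def test_static_calibration_is_deterministic(session):
    c1 = static_calibration(session.static, session.anthro)
    c2 = static_calibration(session.static, session.anthro)
    assert np.array_equal(c1.hjc_offset, c2.hjc_offset)
    assert c1.foot_pitch_offset == c2.foot_pitch_offset


def test_static_pitch_offset_matches_foot_flat_geometry(session):
    """Standing foot-flat: the pitch offset equals the anatomical foot pitch."""
    a = session.anthro
    expected = np.degrees(np.arcsin(min(a.ankle_width, 0.6 * a.foot_length) / a.foot_length))
    calib = static_calibration(session.static, a)
    assert calib.foot_pitch_offset == pytest.approx(expected, abs=1e-9)
    assert calib.foot_rotation_offset == pytest.approx(0.0, abs=1e-9)


def test_static_calibration_invariant_to_yaw(session):
    """Rotating the static trial 30 degrees about vertical changes nothing."""
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    rotated = MarkerTrajectorySet(
        session.static.labels,
        np.einsum("ij,fmj->fmi", R, session.static.positions),
        session.static.rate,
    )
    c0 = static_calibration(session.static, session.anthro)
    c1 = static_calibration(rotated, session.anthro)
    assert c1.foot_pitch_offset == pytest.approx(c0.foot_pitch_offset, abs=1e-9)
    assert c1.foot_rotation_offset == pytest.approx(c0.foot_rotation_offset, abs=1e-9)


def test_missing_marker_reported_by_name(session):
    keep = [l for l in session.static.labels if l != "LKNE"]
    idx = [session.static.labels.index(l) for l in keep]
    broken = MarkerTrajectorySet(
        tuple(keep), session.static.positions[:, idx, :], session.static.rate
    )
    with pytest.raises(MissingMarkerError, match="LKNE"):
        static_calibration(broken, session.anthro)


# ---------------------------------------------------------------- kinematics

def test_round_trip_recovers_generating_angles(session):
    """Noise-free forward-kinematics trial: every angle within 0.5 deg RMS."""
    curves = compute_kinematics(session.dynamic, session.calibration)
    for name in ANGLE_NAMES:
        rms = np.sqrt(np.mean((curves[name] - session.truth[name]) ** 2))
        assert rms < 0.5, f"{name}: {rms:.3f} deg"
        assert rms < 1e-9  # shared conventions make the recovery exact


def test_segment_frames_neutral_pose_geometry(session):
    """Static pose: vertical femur, shank length between knee and ankle centres."""
    ch = segment_frames(session.static, session.calibration)
    assert np.allclose(ch["R_femur"][0][:, 2], [0, 0, 1], atol=1e-9)
    d = np.linalg.norm(ch["kjc"] - ch["ajc"], axis=-1)
    assert np.allclose(d, session.anthro.shank_length, atol=1e-6)
    rho = session.anthro.knee_chord_radius
    knee_dist = np.linalg.norm(ch["kjc"] - session.static["LKNE"], axis=-1)
    assert np.allclose(knee_dist, rho, atol=1e-6)


def test_chord_constraints_hold_every_dynamic_frame(session):
    """|KJC-LKNE| = knee chord radius and right angle at KJC, all frames."""
    ch = segment_frames(session.dynamic, session.calibration)
    rho = session.anthro.knee_chord_radius
    knee = session.dynamic["LKNE"]
    assert np.max(np.abs(np.linalg.norm(ch["kjc"] - knee, axis=-1) - rho)) < 1e-6
    dots = np.sum((ch["hjc"] - ch["kjc"]) * (knee - ch["kjc"]), axis=-1)
    assert np.max(np.abs(dots)) < 1e-6 * session.anthro.thigh_length * rho


def test_joint_angles_invariant_to_rigid_transform(session):
    """Translating+yawing the whole session leaves joint angles unchanged;
    pelvis yaw-like angles shift by the applied yaw."""
    yaw = 25.0
    R = Rotation.from_euler("z", yaw, degrees=True).as_matrix()
    t = np.array([500.0, -300.0, 40.0])

    def move(trial):
        return MarkerTrajectorySet(
            trial.labels,
            np.einsum("ij,fmj->fmi", R, trial.positions) + t,
            trial.rate,
        )

    calib2 = static_calibration(move(session.static), session.anthro)
    c0 = compute_kinematics(session.dynamic, session.calibration)
    c1 = compute_kinematics(move(session.dynamic), calib2)
    for name in ANGLE_NAMES:
        if name in ("pelvis_rotation",):
            continue  # measured against the lab, shifts with the yaw below
        assert np.allclose(c1[name], c0[name], atol=1e-6), name
    # pelvis rotation is lab-referenced: shifted by the yaw (a counter-
    # clockwise yaw moves the left side backward, so the shift is -yaw)
    assert np.allclose(c1["pelvis_rotation"] - c0["pelvis_rotation"], -yaw, atol=1e-6)
    # foot progression is measured against the direction of walking: unchanged
    assert np.allclose(c1["foot_progression"], c0["foot_progression"], atol=1e-6)


def test_single_axis_hip_rotation_changes_only_hip_rotation(session):
    """Rotating the femur about its long axis by 10 degrees reads as 10
    degrees of hip rotation with zero flexion/adduction."""
    from cgmsens.geometry import euler_yxz, relative_rotation, rotation_yxz

    R_rel = rotation_yxz(0.0, 0.0, np.radians(-10.0))
    a, b, c = euler_yxz(R_rel)
    assert np.degrees(-c) == pytest.approx(10.0, abs=1e-9)
    assert abs(a) < 1e-12 and abs(b) < 1e-12


# ---------------------------------------------------------------- normalization

def test_normalize_identity_when_cycle_is_already_101_frames():
    y = np.sin(np.linspace(0, 2 * np.pi, 101))
    curves = KinematicCurves({"knee_flexion": y}, domain="frames")
    events = GaitEvents(strikes=(0, 100))
    out = normalize_cycle(curves, events)
    assert np.allclose(out["knee_flexion"][0], y, atol=1e-12)


def test_normalize_linear_ramp_preserves_endpoints():
    y = np.linspace(5.0, 25.0, 73)
    out = normalize_cycle(
        KinematicCurves({"hip_flexion": y}, domain="frames"),
        GaitEvents(strikes=(0, 72)),
    )[("hip_flexion")]
    assert out.shape == (1, 101)
    assert np.allclose(out[0], np.linspace(5.0, 25.0, 101), atol=1e-9)


def test_normalize_constant_curve_and_multiple_cycles(session):
    y = np.full(201, 7.5)
    out = normalize_cycle(
        KinematicCurves({"pelvis_tilt": y}, domain="frames"),
        GaitEvents(strikes=(0, 100, 200)),
    )["pelvis_tilt"]
    assert out.shape == (2, 101)
    assert np.allclose(out, 7.5)


def test_normalize_requires_a_complete_cycle():
    y = np.zeros(50)
    with pytest.raises(ValidationError):
        normalize_cycle(
            KinematicCurves({"pelvis_tilt": y}, domain="frames"),
            GaitEvents(strikes=(0, 100)),
        )
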