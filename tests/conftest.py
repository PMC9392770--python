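from dataclasses import dataclass

import pytest

from cgmsens import (
    Anthropometry,
    GaitEvents,
    KinematicCurves,
    MarkerTrajectorySet,
    make_anthropometry,
    forward_kinematics,
    static_calibration,
)
from cgmsens.cgm import Calibration
from cgmsens.synthetic import default_template


@dataclass
class Session:
    """One synthetic capture session with ground truth."""

    anthro: Anthropometry
    static: MarkerTrajectorySet
    dynamic: MarkerTrajectorySet
    events: GaitEvents
    truth: KinematicCurves
    calibration: Calibration


@pytest.fixture(scope="session")
def child_anthro() -> Anthropometry:
    return make_anthropometry("child")


@pytest.fixture(scope="session")
def session(child_anthro) -> Session:
    """Noise-free two-cycle walking trial of the default child subject."""
    static, dynamic, events, truth = forward_kinematics(
        child_anthro, default_template(n_cycles=2), rate=100.0, seed=11
    )
    calib = static_calibration(static, child_anthro)
    return Session(child_anthro, static, dynamic, events, truth, calib)
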