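"""In-memory containers: marker trajectories, gait events, joint-angle curves.

Laboratory axes are X anterior (direction of progression), Y left, Z up;
coordinates in mm, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MissingMarkerError, ValidationError

__all__ = [
    "MarkerTrajectorySet",
    "GaitEvents",
    "KinematicCurves",
    "ANGLE_NAMES",
    "GPS_VARIABLES",
    "REQUIRED_MARKERS",
]

#: Markers required to define the left lower limb (SACR may be supplied as
#: the posterior-iliac-spine midpoint, see ``cgm.sacrum_virtual_marker``).
REQUIRED_MARKERS = ("LASI", "RASI", "SACR", "LTHI", "LKNE", "LTIB", "LANK", "LTOE")

#: The reported left-side angle set (order fixed; used for the overall RMSD).
ANGLE_NAMES = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "knee_varus",
    "knee_rotation",
    "ankle_dorsiflexion",
    "ankle_rotation",
    "foot_progression",
)

#: The nine single-side Gait Profile Score variables.
GPS_VARIABLES = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)


@dataclass
class MarkerTrajectorySet:
    """Labelled 3-D marker positions over frames, laboratory frame, mm."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_frames, n_markers, 3)
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ValidationError("positions second axis must match number of labels")
        if self.positions.shape[0] < 1:
            raise ValidationError("a trial needs at least one frame")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("marker labels must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("marker positions must all be finite")
        if not self.rate > 0:
            raise ValidationError("rate must be positive")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __getitem__(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        try:
            return self.positions[:, self._index[label], :]
        except KeyError:
            raise MissingMarkerError(label) from None

    def require(self, *labels: str) -> None:
        missing = [lab for lab in labels if lab not in self._index]
        if missing:
            raise MissingMarkerError(*missing)

    def with_marker(self, label: str, positions: np.ndarray) -> "MarkerTrajectorySet":
        """Return a copy with ``label`` appended (or replaced)."""
        positions = np.asarray(positions, dtype=float)
        if label in self._index:
            new = self.positions.copy()
            new[:, self._index[label], :] = positions
            return MarkerTrajectorySet(self.labels, new, self.rate)
        new = np.concatenate([self.positions, positions[:, None, :]], axis=1)
        return MarkerTrajectorySet(self.labels + (label,), new, self.rate)

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(self.labels, self.positions.copy(), self.rate)


@dataclass(frozen=True)
class GaitEvents:
    """Left-side foot-strike and foot-off frame indices."""

    strikes: tuple[int, ...]
    offs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "strikes", tuple(int(s) for s in self.strikes))
        object.__setattr__(self, "offs", tuple(int(o) for o in self.offs))
        if len(self.strikes) < 2:
            raise ValidationError("need at least two foot strikes (one full cycle)")
        if any(b <= a for a, b in zip(self.strikes, self.strikes[1:])):
            raise ValidationError("foot strikes must be strictly increasing")
        if any(b <= a for a, b in zip(self.offs, self.offs[1:])):
            raise ValidationError("foot offs must be strictly increasing")
        # strikes and offs must alternate: exactly one off inside each cycle
        for off in self.offs:
            if not any(a < off < b for a, b in zip(self.strikes, self.strikes[1:])):
                if off <= self.strikes[0] or off >= self.strikes[-1]:
                    continue  # events outside the analysed cycles are tolerated
                raise ValidationError("foot offs must alternate with strikes")

    @property
    def n_cycles(self) -> int:
        return len(self.strikes) - 1


@dataclass
class KinematicCurves:
    """Named joint-angle series in degrees.

    ``domain`` is ``"frames"`` for raw per-frame curves (1-D arrays) or
    ``"cycle"`` for time-normalized curves with shape (n_cycles, 101).
    """

    data: dict[str, np.ndarray]
    domain: str = "frames"
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.domain not in ("frames", "cycle"):
            raise ValidationError("domain must be 'frames' or 'cycle'")
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"angle curve {name!r} contains non-finite values")
            if self.domain == "cycle":
                arr = np.atleast_2d(arr)
                if arr.shape[1] != 101:
                    raise ValidationError(
                        f"normalized curve {name!r} must have 101 points per cycle"
                    )
            clean[name] = arr
        self.data = clean

    @property
    def angles(self) -> tuple[str, ...]:
        return tuple(self.data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __contains__(self, name: str) -> bool:
        return name in self.data

    def mean_cycle(self) -> dict[str, np.ndarray]:
        """Per-angle average across cycles; requires the normalized domain."""
        if self.domain != "cycle":
            raise ValidationError("mean_cycle is defined for cycle-normalized curves")
        return {name: arr.mean(axis=0) for name, arr in self.data.items()}
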