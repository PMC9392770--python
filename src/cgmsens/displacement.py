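"""Virtual marker-displacement grid: enumeration, application, batch runs.

Each of the eight left-limb markers can stay at its original position
(``ORIG``) or move by a fixed magnitude (default 10 mm) in one of four
90-degree-spaced directions within its main plane of action, expressed in
the reference frame of the segment that owns the marker:

* pelvic markers (LASI, RASI, SACR): coronal plane — lateral/medial (D0,
  D180) and proximal/distal (D90, D270);
* thigh/shank markers (LTHI, LKNE, LTIB, LANK): sagittal plane —
  anterior/posterior (D0, D180) and proximal/distal (D90, D270);
* toe marker (LTOE): transverse plane — lateral/medial (D0, D180) and
  anterior/posterior (D90, D270).

The angular-code-to-anatomical-direction mapping is a documented
convention; since each axis is enumerated in both signs the aggregate
statistics do not depend on it.  Offsets are expressed in the segment
frames computed from the *undisplaced* trial and the same local offset is
applied to the static and dynamic trials, i.e. the misplacement is
consistent across a capture session.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .anthropometry import Anthropometry
from .cgm import (
    compute_kinematics,
    estimate_hjc,
    normalize_cycle,
    sacrum_virtual_marker,
    static_calibration,
    _chain,
)
from .exceptions import CgmSensError, ValidationError
from .metrics import SimulationResult, categorize, gps as gps_score, overall_rmsd, rmsd
from .trial import ANGLE_NAMES, GaitEvents, KinematicCurves, MarkerTrajectorySet

__all__ = [
    "MARKERS",
    "CODES",
    "DisplacementSpec",
    "DisplacementGrid",
    "direction_vector",
    "grid",
    "sample_grid",
    "apply_displacement",
    "run_batch",
]

log = logging.getLogger(__name__)

MARKERS = ("LASI", "RASI", "SACR", "LTHI", "LKNE", "LTIB", "LANK", "LTOE")
CODES = ("ORIG", "D0", "D90", "D180", "D270")

SEGMENT_OF = {
    "LASI": "pelvis",
    "RASI": "pelvis",
    "SACR": "pelvis",
    "LTHI": "femur",
    "LKNE": "femur",
    "LTIB": "tibia",
    "LANK": "tibia",
    "LTOE": "foot",
}

# unit vectors in the owning segment frame (x anterior, y lateral-left, z proximal)
_PLANE_VECTORS = {
    "pelvis": {
        "D0": (0.0, 1.0, 0.0),
        "D90": (0.0, 0.0, 1.0),
        "D180": (0.0, -1.0, 0.0),
        "D270": (0.0, 0.0, -1.0),
    },
    "sagittal": {
        "D0": (1.0, 0.0, 0.0),
        "D90": (0.0, 0.0, 1.0),
        "D180": (-1.0, 0.0, 0.0),
        "D270": (0.0, 0.0, -1.0),
    },
    "foot": {
        "D0": (0.0, 1.0, 0.0),
        "D90": (1.0, 0.0, 0.0),
        "D180": (0.0, -1.0, 0.0),
        "D270": (-1.0, 0.0, 0.0),
    },
}


def direction_vector(marker: str, code: str) -> np.ndarray:
    """Unit displacement direction for ``marker`` in its segment frame."""
    if marker not in MARKERS:
        raise ValidationError(f"unknown marker {marker!r}")
    if code not in CODES:
        raise ValidationError(f"unknown direction code {code!r}")
    if code == "ORIG":
        return np.zeros(3)
    seg = SEGMENT_OF[marker]
    table = _PLANE_VECTORS["pelvis" if seg == "pelvis" else "foot" if seg == "foot" else "sagittal"]
    return np.array(table[code])


@dataclass(frozen=True)
class DisplacementSpec:
    """One point of the displacement grid: a direction code per marker."""

    codes: tuple[str, ...]
    magnitude: float = 10.0

    def __post_init__(self) -> None:
        if len(self.codes) != len(MARKERS):
            raise ValidationError(f"need one code per marker ({len(MARKERS)})")
        bad = [c for c in self.codes if c not in CODES]
        if bad:
            raise ValidationError(f"invalid direction code(s): {bad}")
        if self.magnitude < 0:
            raise ValidationError("magnitude must be non-negative")

    @classmethod
    def null(cls, magnitude: float = 10.0) -> "DisplacementSpec":
        return cls(("ORIG",) * len(MARKERS), magnitude)

    @classmethod
    def single(cls, marker: str, code: str, magnitude: float = 10.0) -> "DisplacementSpec":
        if marker not in MARKERS:
            raise ValidationError(f"unknown marker {marker!r}")
        codes = tuple(code if m == marker else "ORIG" for m in MARKERS)
        return cls(codes, magnitude)

    @property
    def is_null(self) -> bool:
        return all(c == "ORIG" for c in self.codes)

    @property
    def displaced_markers(self) -> tuple[str, ...]:
        return tuple(m for m, c in zip(MARKERS, self.codes) if c != "ORIG")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(MARKERS, self.codes))


@dataclass(frozen=True)
class DisplacementGrid:
    """The full ``s^m`` grid in deterministic lexicographic order.

    The first ``s`` codes of ``CODES`` are enumerated per marker with the
    first marker most significant, so element 0 is always the null spec.
    """

    s: int = 5
    markers: tuple[str, ...] = MARKERS
    magnitude: float = 10.0

    def __post_init__(self) -> None:
        if not 1 <= self.s <= len(CODES):
            raise ValidationError(f"s must be between 1 and {len(CODES)}")
        if not self.markers:
            raise ValidationError("markers must be non-empty")
        unknown = set(self.markers) - set(MARKERS)
        if unknown:
            raise ValidationError(f"unknown marker(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return self.s ** len(self.markers)

    def _codes_for(self, digits) -> tuple[str, ...]:
        per = dict(zip(self.markers, digits))
        return tuple(CODES[per[m]] if m in per else "ORIG" for m in MARKERS)

    def __getitem__(self, i: int) -> DisplacementSpec:
        n = len(self)
        if not 0 <= i < n:
            raise IndexError(i)
        digits = []
        for _ in self.markers:
            digits.append(i % self.s)
            i //= self.s
        digits.reverse()  # first marker most significant
        return DisplacementSpec(self._codes_for(digits), self.magnitude)

    def __iter__(self):
        for digits in itertools.product(range(self.s), repeat=len(self.markers)):
            yield DisplacementSpec(self._codes_for(digits), self.magnitude)


def grid(
    s: int = 5, markers: tuple[str, ...] = MARKERS, magnitude: float = 10.0
) -> DisplacementGrid:
    """The combinatorial grid of ``s`` positions for each of ``m`` markers."""
    return DisplacementGrid(s=s, markers=tuple(markers), magnitude=magnitude)


def sample_grid(
    gridspec: DisplacementGrid, n: int, seed: int | None = None
) -> list[DisplacementSpec]:
    """Uniform sample of ``n`` grid points without replacement.

    The null spec is always included (as the first element); the remaining
    ``n - 1`` points are drawn uniformly from the rest of the grid.
    """
    size = len(gridspec)
    if n < 1:
        raise ValidationError("sample size must be at least 1")
    if n > size:
        raise ValidationError(f"sample size {n} exceeds grid size {size}")
    if n == size:
        idx = np.arange(size)
    else:
        rng = np.random.default_rng(seed)
        idx = np.concatenate(
            [[0], 1 + rng.choice(size - 1, size=n - 1, replace=False)]
        )
    return [gridspec[int(i)] for i in idx]


def _segment_rotations(
    trial: MarkerTrajectorySet, anthro: Anthropometry
) -> dict[str, np.ndarray]:
    """Per-frame rotation matrices of the four segments from original markers."""
    ch = _chain(sacrum_virtual_marker(trial), anthro, estimate_hjc(anthro))
    return {
        "pelvis": ch["R_pelvis"],
        "femur": ch["R_femur"],
        "tibia": ch["R_tibia"],
        "foot": ch["R_foot"],
    }


def apply_displacement(
    static: MarkerTrajectorySet,
    dynamic: MarkerTrajectorySet,
    spec: DisplacementSpec,
    static_frames: dict[str, np.ndarray],
    dynamic_frames: dict[str, np.ndarray],
) -> tuple[MarkerTrajectorySet, MarkerTrajectorySet]:
    """Displace markers by the spec's local offsets in both trials.

    ``static_frames`` / ``dynamic_frames`` are the per-frame segment
    rotations computed from the *undisplaced* trials (see
    :func:`_segment_rotations`); the same segment-local offset is applied
    to every frame of both trials.  The null spec returns the inputs
    unchanged (bit-for-bit).
    """
    if spec.is_null:
        return static, dynamic
    out = []
    for trial, frames in ((static, static_frames), (dynamic, dynamic_frames)):
        new = trial.copy()
        for marker, code in zip(MARKERS, spec.codes):
            if code == "ORIG":
                continue
            vec = spec.magnitude * direction_vector(marker, code)
            R = frames[SEGMENT_OF[marker]]
            if R.shape[0] != new.n_frames:
                raise ValidationError(
                    "segment frames do not match the trial's frame count"
                )
            new = new.with_marker(marker, new[marker] + np.einsum("fij,j->fi", R, vec))
        out.append(new)
    return out[0], out[1]


@dataclass
class BatchContext:
    """Everything needed to evaluate displacement specs on one session."""

    static: MarkerTrajectorySet
    dynamic: MarkerTrajectorySet
    events: GaitEvents
    anthro: Anthropometry
    static_frames: dict[str, np.ndarray] = field(repr=False, default=None)
    dynamic_frames: dict[str, np.ndarray] = field(repr=False, default=None)
    reference: dict[str, np.ndarray] = field(repr=False, default=None)
    ref_population_mean: dict[str, np.ndarray] | None = field(repr=False, default=None)


def _prepare(static, dynamic, events, anthro, ref_population_mean) -> BatchContext:
    static = sacrum_virtual_marker(static)
    dynamic = sacrum_virtual_marker(dynamic)
    calib = static_calibration(static, anthro)
    ref = normalize_cycle(compute_kinematics(dynamic, calib), events).mean_cycle()
    return BatchContext(
        static=static,
        dynamic=dynamic,
        events=events,
        anthro=anthro,
        static_frames=_segment_rotations(static, anthro),
        dynamic_frames=_segment_rotations(dynamic, anthro),
        reference=ref,
        ref_population_mean=ref_population_mean,
    )


def _evaluate_spec(
    ctx: BatchContext, spec: DisplacementSpec, return_curves: bool
) -> SimulationResult | None:
    try:
        s2, d2 = apply_displacement(
            ctx.static, ctx.dynamic, spec, ctx.static_frames, ctx.dynamic_frames
        )
        calib = static_calibration(s2, ctx.anthro)
        curves = normalize_cycle(compute_kinematics(d2, calib), ctx.events)
        mean = curves.mean_cycle()
    except CgmSensError as exc:
        log.warning("spec %s failed and was skipped: %s", spec.codes, exc)
        return None
    per_angle = {a: rmsd(ctx.reference[a], mean[a]) for a in ANGLE_NAMES}
    overall = overall_rmsd(per_angle)
    gps_val = gvs_val = None
    if ctx.ref_population_mean is not None:
        gvs_val, gps_val = gps_score(mean, ctx.ref_population_mean)
    return SimulationResult(
        spec=spec,
        rmsd_per_angle=per_angle,
        overall_rmsd=overall,
        category=categorize(overall),
        gps=gps_val,
        gvs=gvs_val,
        curves=curves if return_curves else None,
    )


def _evaluate_block(ctx, specs, return_curves):
    return [_evaluate_spec(ctx, s, return_curves) for s in specs]


def run_batch(
    static: MarkerTrajectorySet,
    dynamic: MarkerTrajectorySet,
    events: GaitEvents,
    anthro: Anthropometry,
    specs: list[DisplacementSpec],
    workers: int = 1,
    *,
    ref_population_mean: dict[str, np.ndarray] | None = None,
    return_curves: bool = False,
    progress_every: int = 0,
) -> list[SimulationResult]:
    """Evaluate displacement specs against the undisplaced reference.

    For each spec the static trial is displaced and recalibrated, the
    dynamic trial is displaced and its kinematics recomputed and
    cycle-normalized, and RMSD/category/GPS metrics are taken against the
    null-spec kinematics of the same session.  Result order matches spec
    order regardless of ``workers``; specs failing with degenerate
    geometry are logged and skipped.
    """
    specs = list(specs)
    ctx = _prepare(static, dynamic, events, anthro, ref_population_mean)
    if workers == 1:
        results = []
        for i, spec in enumerate(specs):
            results.append(_evaluate_spec(ctx, spec, return_curves))
            if progress_every and (i + 1) % progress_every == 0:
                log.info("evaluated %d/%d specs", i + 1, len(specs))
    else:
        block = max(1, math.ceil(len(specs) / (workers * 8)))
        blocks = [specs[i : i + block] for i in range(0, len(specs), block)]
        nested = Parallel(n_jobs=workers)(
            delayed(_evaluate_block)(ctx, b, return_curves) for b in blocks
        )
        results = [r for b in nested for r in b]
    return [r for r in results if r is not None]
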