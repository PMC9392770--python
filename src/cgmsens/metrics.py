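"""RMSD statistics, variability categories, Gait Profile Score, corridors.

The RMSD angle of a simulation is the root-mean-square difference between
the original and the simulated joint-angle curve over the normalized gait
cycle.  Simulations are binned into four clinically motivated variability
categories: (1) <= 2 deg (optimal), (2) > 2-5 deg (acceptable),
(3) > 5-10 deg, (4) > 10 deg.

The Gait Profile Score (GPS) summarizes how far a subject's kinematics sit
from an asymptomatic reference: per variable the Gait Variable Score (GVS)
is the RMS difference from the reference mean curve, and the GPS is the
RMS of the GVS vector over the nine single-side variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .trial import ANGLE_NAMES, GPS_VARIABLES, KinematicCurves

if TYPE_CHECKING:  # pragma: no cover
    from .displacement import DisplacementSpec

__all__ = [
    "SimulationResult",
    "CATEGORY_THRESHOLDS",
    "rmsd",
    "categorize",
    "overall_rmsd",
    "gps",
    "category_distribution",
    "worst_cases",
    "single_marker_table",
    "corridors",
]

#: Category boundaries in degrees; bins are (0, 2], (2, 5], (5, 10], (10, inf).
CATEGORY_THRESHOLDS = (2.0, 5.0, 10.0)


@dataclass
class SimulationResult:
    """Metrics of one displacement simulation."""

    spec: "DisplacementSpec"
    rmsd_per_angle: dict[str, float]
    overall_rmsd: float
    category: int
    gps: float | None = None
    gvs: dict[str, float] | None = None
    curves: KinematicCurves | None = field(default=None, repr=False)


def rmsd(reference: np.ndarray, simulated: np.ndarray) -> float:
    """Root-mean-square deviation between two curves of equal length."""
    reference = np.asarray(reference, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if reference.shape != simulated.shape:
        raise ValidationError(
            f"curve shapes differ: {reference.shape} vs {simulated.shape}"
        )
    return float(np.sqrt(np.mean((reference - simulated) ** 2)))


def categorize(x: float, thresholds: Sequence[float] = CATEGORY_THRESHOLDS) -> int:
    """Variability category 1-4 of an RMSD value (boundaries belong down)."""
    if x < 0 or not np.isfinite(x):
        raise ValidationError("RMSD must be finite and non-negative")
    t1, t2, t3 = thresholds
    if x <= t1:
        return 1
    if x <= t2:
        return 2
    if x <= t3:
        return 3
    return 4


def overall_rmsd(
    per_angle: dict[str, float], angles: Sequence[str] = ANGLE_NAMES
) -> float:
    """Arithmetic mean RMSD over the configured angle set."""
    if not angles:
        raise ValidationError("angle set must be non-empty")
    missing = [a for a in angles if a not in per_angle]
    if missing:
        raise ValidationError(f"missing RMSD for angle(s): {missing}")
    return float(np.mean([per_angle[a] for a in angles]))


def gps(
    subject: dict[str, np.ndarray] | KinematicCurves,
    reference_mean: dict[str, np.ndarray],
    variables: Sequence[str] = GPS_VARIABLES,
) -> tuple[dict[str, float], float]:
    """Gait Variable Scores and the Gait Profile Score.

    ``subject`` maps variables to 101-point curves (or is a normalized
    :class:`KinematicCurves`, averaged across cycles); ``reference_mean``
    maps the same variables to the reference-population mean curves.
    """
    if isinstance(subject, KinematicCurves):
        subject = subject.mean_cycle()
    missing = [v for v in variables if v not in subject or v not in reference_mean]
    if missing:
        raise ValidationError(f"missing GPS variable(s): {missing}")
    gvs = {v: rmsd(reference_mean[v], subject[v]) for v in variables}
    return gvs, float(np.sqrt(np.mean(np.square(list(gvs.values())))))


def category_distribution(
    results: Iterable[SimulationResult], angle: str | None = None
) -> np.ndarray:
    """Percentage of simulations per variability category (sums to 100).

    With ``angle`` the per-angle RMSD is binned; otherwise the overall RMSD.
    """
    results = list(results)
    if not results:
        raise ValidationError("need at least one result")
    values = [
        r.rmsd_per_angle[angle] if angle is not None else r.overall_rmsd
        for r in results
    ]
    counts = np.bincount([categorize(v) - 1 for v in values], minlength=4)
    return 100.0 * counts / counts.sum()


def worst_cases(results: Iterable[SimulationResult], k: int = 10) -> list[SimulationResult]:
    """Top-``k`` simulations by overall RMSD (descending).

    Ties are broken deterministically by the spec's code tuple.
    """
    results = list(results)
    if k > len(results):
        raise ValidationError(f"k={k} exceeds the number of results ({len(results)})")
    return sorted(results, key=lambda r: (-r.overall_rmsd, r.spec.codes))[:k]


def single_marker_table(
    results: Iterable[SimulationResult],
    threshold: float = 2.0,
    masked: bool = True,
) -> pd.DataFrame:
    """Mean RMSD per (marker, direction, angle) for single-marker simulations.

    Rows are indexed by (marker, direction code); only results displacing
    exactly one marker contribute (averaged over everything else: subjects,
    trials, repeats).  Cells not strictly greater than ``threshold`` are
    masked to NaN when ``masked`` is true, mirroring how such tables are
    reported clinically.  All 4 directions of all 8 markers must be present.
    """
    from .displacement import CODES, MARKERS  # local import to avoid module cycle

    cells: dict[tuple[str, str], list[dict[str, float]]] = {}
    for r in results:
        displaced = r.spec.displaced_markers
        if len(displaced) != 1:
            continue
        marker = displaced[0]
        code = r.spec.as_dict()[marker]
        cells.setdefault((marker, code), []).append(r.rmsd_per_angle)

    expected = [(m, c) for m in MARKERS for c in CODES if c != "ORIG"]
    missing = [mc for mc in expected if mc not in cells]
    if missing:
        raise ValidationError(f"missing single-marker specs: {missing}")

    rows = {}
    for key in expected:
        per = cells[key]
        rows[key] = {a: float(np.mean([p[a] for p in per])) for a in ANGLE_NAMES}
    table = pd.DataFrame.from_dict(rows, orient="index")[list(ANGLE_NAMES)]
    table.index = pd.MultiIndex.from_tuples(table.index, names=["marker", "direction"])
    if masked:
        table = table.where(table > threshold)
    return table


def corridors(
    reference: Sequence[KinematicCurves],
    simulated: Sequence[SimulationResult],
) -> dict[str, pd.DataFrame]:
    """Inter-trial SD band and maximal-deviation band per cycle point.

    ``reference`` holds the normalized original curves of >= 2 trials (all
    cycles pooled for the per-point SD).  ``simulated`` must carry curves
    (``run_batch(..., return_curves=True)``); the second band is the
    maximum absolute simulated-minus-original deviation across specs.
    Returns one DataFrame per angle with columns ``mean``,
    ``inter_trial_sd`` and ``max_abs_dev``.
    """
    reference = list(reference)
    if len(reference) < 2:
        raise ValidationError("need at least two reference trials for the SD band")
    simulated = [r for r in simulated if r.curves is not None]
    if not simulated:
        raise ValidationError("simulated results must carry curves")

    angles = reference[0].angles
    out: dict[str, pd.DataFrame] = {}
    for angle in angles:
        stack = np.vstack([c[angle] for c in reference])
        ref_mean = stack.mean(axis=0)
        dev = np.max(
            np.abs(
                np.vstack([r.curves.mean_cycle()[angle] for r in simulated]) - ref_mean
            ),
            axis=0,
        )
        out[angle] = pd.DataFrame(
            {
                "percent": np.arange(101),
                "mean": ref_mean,
                "inter_trial_sd": stack.std(axis=0, ddof=1),
                "max_abs_dev": dev,
            }
        )
    return out


def worst_cases_summary(worst: Sequence[SimulationResult]) -> str:
    """JSON-serializable summary of a worst-case list."""
    payload = [
        {
            "codes": dict(r.spec.as_dict()),
            "magnitude_mm": r.spec.magnitude,
            "overall_rmsd_deg": r.overall_rmsd,
            "category": r.category,
            "gps_deg": r.gps,
            "rmsd_per_angle_deg": r.rmsd_per_angle,
        }
        for r in worst
    ]
    return json.dumps(payload, indent=2)
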