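"""Plain-text file formats: trial CSV dialect, YAML config, results CSV.

Trial CSV dialect (long format): comment header lines ``# key: value``
carrying provenance (rate, events, seed, config hash, package version),
then ``frame,marker,x,y,z`` rows with coordinates in mm and laboratory
axes X anterior, Y left, Z up.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import Anthropometry
from .exceptions import ValidationError
from .metrics import SimulationResult, categorize, overall_rmsd
from .trial import ANGLE_NAMES, GaitEvents, KinematicCurves, MarkerTrajectorySet

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_anthropometry_yaml",
    "read_anthropometry_yaml",
    "write_curves_csv",
    "read_curves_csv",
    "write_results_csv",
    "read_results_csv",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Short deterministic hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(meta: dict | None) -> dict:
    out = {"package": f"cgmsens {__version__}"}
    if meta:
        out.update(meta)
    return out


def write_trial_csv(
    path: str | Path,
    trial: MarkerTrajectorySet,
    events: GaitEvents | None = None,
    meta: dict | None = None,
) -> None:
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in _provenance(meta).items()]
    lines.append(f"# rate: {trial.rate!r}")
    if events is not None:
        lines.append(f"# strikes: {','.join(map(str, events.strikes))}")
        if events.offs:
            lines.append(f"# offs: {','.join(map(str, events.offs))}")
    lines.append("frame,marker,x,y,z")
    n = trial.n_frames
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i, label in enumerate(trial.labels):
            pos = trial.positions[:, i, :]
            block = pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "marker": label,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                }
            )
            block.to_csv(fh, header=False, index=False, float_format="%.6f")


def _read_header(path: Path) -> dict[str, str]:
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_trial_csv(path: str | Path) -> tuple[MarkerTrajectorySet, GaitEvents | None]:
    path = Path(path)
    meta = _read_header(path)
    if "rate" not in meta:
        raise ValidationError(f"{path} has no '# rate:' header line")
    df = pd.read_csv(path, comment="#")
    required = {"frame", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path} lacks columns {sorted(required - set(df.columns))}")
    labels = tuple(dict.fromkeys(df["marker"]))
    n_frames = int(df["frame"].max()) + 1
    positions = np.full((n_frames, len(labels), 3), np.nan)
    for i, label in enumerate(labels):
        sub = df[df["marker"] == label].sort_values("frame")
        positions[sub["frame"].to_numpy(), i, :] = sub[["x", "y", "z"]].to_numpy()
    trial = MarkerTrajectorySet(labels, positions, float(meta["rate"]))
    events = None
    if "strikes" in meta:
        strikes = tuple(int(s) for s in meta["strikes"].split(","))
        offs = tuple(int(s) for s in meta.get("offs", "").split(",") if s)
        events = GaitEvents(strikes=strikes, offs=offs)
    return trial, events


def write_anthropometry_yaml(path: str | Path, anthro: Anthropometry) -> None:
    data = {k: float(v) for k, v in vars(anthro).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_anthropometry_yaml(path: str | Path) -> Anthropometry:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path} does not hold a key-value mapping")
    return Anthropometry(**{k: float(v) for k, v in data.items()})


def write_curves_csv(
    path: str | Path, curves: KinematicCurves, meta: dict | None = None
) -> None:
    if curves.domain != "cycle":
        raise ValidationError("only cycle-normalized curves are written to CSV")
    rows = []
    for angle, arr in curves.data.items():
        for c in range(arr.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "angle": angle,
                        "cycle": c,
                        "percent": np.arange(101),
                        "value": arr[c],
                    }
                )
            )
    path = Path(path)
    with path.open("w") as fh:
        for k, v in _provenance(meta).items():
            fh.write(f"# {k}: {v}\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False, float_format="%.6f")


def read_curves_csv(path: str | Path) -> KinematicCurves:
    df = pd.read_csv(path, comment="#")
    data = {}
    for angle, sub in df.groupby("angle", sort=False):
        cycles = [
            g.sort_values("percent")["value"].to_numpy()
            for _, g in sub.groupby("cycle", sort=True)
        ]
        data[angle] = np.vstack(cycles)
    return KinematicCurves(data, domain="cycle")


_RESULT_FIXED = ["overall_rmsd", "category", "gps", "magnitude"]


def _results_columns() -> list[str]:
    from .displacement import MARKERS

    return list(MARKERS) + _RESULT_FIXED + [f"rmsd_{a}" for a in ANGLE_NAMES]


def write_results_csv(
    path: str | Path,
    results: Iterable[SimulationResult],
    meta: dict | None = None,
    append: bool = False,
) -> None:
    """Stream simulation results to CSV, one row per spec."""
    from .displacement import MARKERS

    path = Path(path)
    cols = _results_columns()
    mode = "a" if append and path.exists() else "w"
    with path.open(mode) as fh:
        if mode == "w":
            for k, v in _provenance(meta).items():
                fh.write(f"# {k}: {v}\n")
            fh.write(",".join(cols) + "\n")
        for r in results:
            row = dict(zip(MARKERS, r.spec.codes))
            row.update(
                overall_rmsd=f"{r.overall_rmsd:.9g}",
                category=r.category,
                gps="" if r.gps is None else f"{r.gps:.9g}",
                magnitude=r.spec.magnitude,
            )
            row.update({f"rmsd_{a}": f"{v:.9g}" for a, v in r.rmsd_per_angle.items()})
            fh.write(",".join(str(row[c]) for c in cols) + "\n")


def read_results_csv(path: str | Path) -> list[SimulationResult]:
    """Reload results; all summary statistics are reproducible from this file."""
    from .displacement import MARKERS, DisplacementSpec

    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        spec = DisplacementSpec(
            tuple(row[m] for m in MARKERS), magnitude=float(row["magnitude"])
        )
        per_angle = {a: float(row[f"rmsd_{a}"]) for a in ANGLE_NAMES}
        gps_val = None if pd.isna(row.get("gps")) else float(row["gps"])
        out.append(
            SimulationResult(
                spec=spec,
                rmsd_per_angle=per_angle,
                overall_rmsd=float(row["overall_rmsd"]),
                category=int(row["category"]),
                gps=gps_val,
            )
        )
    return out


def completed_specs(path: str | Path) -> set[tuple[str, ...]]:
    """Spec code tuples already present in a results CSV (for resuming)."""
    from .displacement import MARKERS

    path = Path(path)
    if not path.exists():
        return set()
    df = pd.read_csv(path, comment="#")
    return {tuple(row[m] for m in MARKERS) for _, row in df.iterrows()}
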