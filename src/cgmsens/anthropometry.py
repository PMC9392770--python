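"""Subject measurements that parameterize joint-centre estimation and the generator.

All lengths are millimetres.  The two presets correspond to a ~150 cm child
(the cohort the synthetic trials emulate) and a ~170 cm adolescent/adult.
With a seed, :func:`make_anthropometry` draws subject-to-subject variation
from truncated normal distributions around the preset means; the wand
stand-offs are drawn uniformly from their documented ranges because wand
placement has no bony landmark and is the least constrained measurement of
the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .exceptions import ValidationError

__all__ = ["Anthropometry", "make_anthropometry", "PRESETS", "WAND_RANGES"]


@dataclass(frozen=True)
class Anthropometry:
    """Lower-limb measurements of one subject (left side), in mm.

    ``thigh_wand_standoff`` / ``shank_wand_standoff`` are the perpendicular
    distances of the wand marker from the segment's coronal chord line
    (hip-centre-to-knee-marker and knee-centre-to-ankle-marker respectively);
    this is the lever arm that governs how strongly an anterior-posterior
    wand misplacement twists the segment frame.
    """

    leg_length: float
    inter_asis: float
    pelvis_depth: float
    knee_width: float
    ankle_width: float
    marker_radius: float
    thigh_length: float
    shank_length: float
    foot_length: float
    thigh_wand_standoff: float
    shank_wand_standoff: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"anthropometry field {f.name!r} must be strictly positive "
                    f"and finite, got {v!r}"
                )
        if self.leg_length < self.thigh_length + self.shank_length - 20.0:
            raise ValidationError(
                "leg_length must be at least thigh_length + shank_length - 20 mm"
            )
        if self.inter_asis >= self.leg_length:
            raise ValidationError("inter_asis must be smaller than leg_length")

    @property
    def knee_chord_radius(self) -> float:
        """Distance from the lateral knee marker centre to the knee joint centre."""
        return self.knee_width / 2.0 + self.marker_radius

    @property
    def ankle_chord_radius(self) -> float:
        """Distance from the lateral ankle marker centre to the ankle joint centre."""
        return self.ankle_width / 2.0 + self.marker_radius


#: Preset means.  Child: ~150 cm stature (thigh+shank ~0.48 x height);
#: adult: ~170 cm.  Markers are 14 mm diameter spheres -> 7 mm radius.
#: inter_asis and pelvis_depth are marker-centre distances: the skeletal
#: breadth/depth plus the anterior/posterior stand-off of markers mounted
#: on their bases (~17 mm per marker on the sagittal depth).
PRESETS: dict[str, dict[str, float]] = {
    "child": dict(
        leg_length=770.0,
        inter_asis=235.0,
        pelvis_depth=170.0,
        knee_width=90.0,
        ankle_width=65.0,
        marker_radius=7.0,
        thigh_length=368.0,
        shank_length=350.0,
        foot_length=150.0,
        thigh_wand_standoff=75.0,
        shank_wand_standoff=60.0,
    ),
    "adult": dict(
        leg_length=880.0,
        inter_asis=255.0,
        pelvis_depth=190.0,
        knee_width=100.0,
        ankle_width=70.0,
        marker_radius=7.0,
        thigh_length=420.0,
        shank_length=395.0,
        foot_length=170.0,
        thigh_wand_standoff=80.0,
        shank_wand_standoff=65.0,
    ),
}

#: Uniform sampling ranges for the wand stand-offs (mm) when a seed is given.
WAND_RANGES: dict[str, tuple[float, float]] = {
    "thigh_wand_standoff": (60.0, 90.0),
    "shank_wand_standoff": (50.0, 70.0),
}

#: Coefficient of variation of the common stature scale / the width draws.
_CV = 0.05
#: Marker radius is a property of the hardware, not the subject.
_FIXED = ("marker_radius",)
#: Lengths tied to stature (scaled together so skeletal invariants hold).
_STATURE_SCALED = (
    "leg_length", "thigh_length", "shank_length", "foot_length",
    "inter_asis", "pelvis_depth",
)
#: Widths drawn independently.
_INDEPENDENT = ("knee_width", "ankle_width")


def make_anthropometry(
    preset: str = "child",
    overrides: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> Anthropometry:
    """Build a validated :class:`Anthropometry`.

    Without a seed the preset means are returned.  With a seed, stature-tied
    lengths share a common normal scale factor (5 % coefficient of
    variation, truncated to +-2.5 sd) so skeletal proportions stay valid,
    joint widths are drawn independently at the same CV, and the wand
    stand-offs are uniform over their documented ranges.  Explicit
    ``overrides`` always win over sampled values.

    Parameters
    ----------
    preset : {"child", "adult", "custom"}
        ``custom`` starts from the child means and requires overrides for
        anything that should differ.
    """
    base_name = "child" if preset == "custom" else preset
    if base_name not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}")
    values = dict(PRESETS[base_name])

    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        scale = float(np.clip(rng.normal(1.0, _CV), 1.0 - 2.5 * _CV, 1.0 + 2.5 * _CV))
        for name in _STATURE_SCALED:
            values[name] = values[name] * scale
        for name in _INDEPENDENT:
            mean = values[name]
            sd = _CV * mean
            values[name] = float(np.clip(rng.normal(mean, sd), mean - 2.5 * sd, mean + 2.5 * sd))
        for name, (lo, hi) in WAND_RANGES.items():
            values[name] = float(rng.uniform(lo, hi))

    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ValidationError(f"unknown anthropometry field(s): {sorted(unknown)}")
        values.update({k: float(v) for k, v in overrides.items()})

    return Anthropometry(**values)


def scaled(anthro: Anthropometry, factor: float) -> Anthropometry:
    """Uniformly scale all length measurements except the marker radius."""
    updates = {
        f.name: getattr(anthro, f.name) * factor
        for f in fields(anthro)
        if f.name not in _FIXED
    }
    return replace(anthro, **updates)
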