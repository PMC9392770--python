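"""Rigid-body geometry primitives: frames, the chord function, Cardan angles.

Rotation matrices store segment axes as columns ``[x, y, z]`` (anterior,
lateral-left, proximal) expressed in the laboratory frame, so ``R`` maps
segment-local coordinates to laboratory coordinates.  All functions accept
arbitrary leading batch dimensions on their point arguments.

Angle decompositions use the mobile Cardan sequence y-x'-z'' (flexion axis
first, then the floating abduction axis, then the long axis), the standard
clinical sequence for lower-limb joints.  Sign conventions for the left
side are documented per joint in :mod:`cgmsens.cgm`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateGeometryError

__all__ = [
    "unit",
    "chord_joint_center",
    "pelvis_frame",
    "segment_frame_from_centres",
    "rotation_yxz",
    "euler_yxz",
    "rotation_zxy",
    "euler_zxy",
    "relative_rotation",
]

_EPS = 1e-12


def unit(v: np.ndarray, *, name: str = "vector") -> np.ndarray:
    """Normalize along the last axis; error on (near-)zero norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        bad = int(np.argmax(n.reshape(-1) < _EPS))
        raise DegenerateGeometryError(f"cannot normalize near-zero {name}", frame=bad)
    return v / n


def chord_joint_center(
    prox: np.ndarray, lat: np.ndarray, wand: np.ndarray, radius: float
) -> np.ndarray:
    """Joint centre from the chord construction.

    Returns the point ``J`` such that

    * ``J`` lies in the plane of ``prox`` (proximal joint centre), ``lat``
      (lateral joint marker) and ``wand`` (wand marker defining the plane),
    * ``|J - lat| = radius``,
    * the angle ``prox - J - lat`` is 90 degrees,
    * ``J`` lies on the opposite side of the prox-lat line from the wand
      (the side where the true joint centre sits when the lateral marker is
      on the flexion axis and the wand stands off laterally).

    With ``radius = 0`` the lateral marker itself is returned.
    """
    prox = np.asarray(prox, dtype=float)
    lat = np.asarray(lat, dtype=float)
    wand = np.asarray(wand, dtype=float)
    if radius < 0:
        raise DegenerateGeometryError("chord radius must be non-negative")
    if radius == 0:
        return np.broadcast_arrays(lat, prox)[0].copy()

    pl = prox - lat
    d = np.linalg.norm(pl, axis=-1, keepdims=True)
    if np.any(d <= radius):
        bad = int(np.argmax((d <= radius).reshape(-1)))
        raise DegenerateGeometryError(
            f"proximal-to-lateral distance must exceed the chord radius {radius}",
            frame=bad,
        )
    u = pl / d
    w = wand - lat
    w_perp = w - np.sum(w * u, axis=-1, keepdims=True) * u
    n = np.linalg.norm(w_perp, axis=-1, keepdims=True)
    if np.any(n < 1e-9):
        bad = int(np.argmax((n < 1e-9).reshape(-1)))
        raise DegenerateGeometryError(
            "prox, lat and wand are collinear; chord plane undefined", frame=bad
        )
    v = w_perp / n
    c = radius / d
    return lat + radius * (c * u - np.sqrt(1.0 - c * c) * v)


def pelvis_frame(
    lasi: np.ndarray, rasi: np.ndarray, sacr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pelvis origin (mid-ASIS) and axes from the three pelvic markers.

    Lateral axis y along RASI->LASI; anterior axis x in the marker plane,
    orthogonal to y, pointing away from the sacrum; z completes the
    right-handed triad (up in the anatomical pose).
    """
    lasi = np.asarray(lasi, dtype=float)
    rasi = np.asarray(rasi, dtype=float)
    sacr = np.asarray(sacr, dtype=float)
    origin = 0.5 * (lasi + rasi)
    y = unit(lasi - rasi, name="inter-ASIS axis")
    a = origin - sacr
    a_perp = a - np.sum(a * y, axis=-1, keepdims=True) * y
    n = np.linalg.norm(a_perp, axis=-1, keepdims=True)
    if np.any(n < 1e-9):
        bad = int(np.argmax((n < 1e-9).reshape(-1)))
        raise DegenerateGeometryError("pelvic markers are collinear", frame=bad)
    x = a_perp / n
    z = np.cross(x, y)
    return origin, np.stack([x, y, z], axis=-1)


def segment_frame_from_centres(
    origin_jc: np.ndarray, prox_jc: np.ndarray, lat_marker: np.ndarray
) -> np.ndarray:
    """Femur/tibia axes from the distal joint centre, proximal centre and
    the lateral marker sitting on the flexion axis.

    z: distal joint centre -> proximal centre (long axis, proximal);
    y: distal joint centre -> lateral marker (flexion axis; orthogonal to z
    by the chord construction, re-orthogonalized for numerical safety);
    x = y cross z (anterior).
    """
    z = unit(np.asarray(prox_jc, float) - origin_jc, name="segment long axis")
    y0 = unit(np.asarray(lat_marker, float) - origin_jc, name="flexion axis")
    x = unit(np.cross(y0, z), name="segment anterior axis")
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


def rotation_yxz(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Rotation matrices ``R = Ry(a) @ Rx(b) @ Rz(c)`` (radians, batched)."""
    a, b, c = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    )
    angles = np.stack([a, b, c], axis=-1)
    return Rotation.from_euler("YXZ", angles.reshape(-1, 3)).as_matrix().reshape(
        angles.shape[:-1] + (3, 3)
    )


def rotation_zxy(c: np.ndarray, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rotation matrices ``R = Rz(c) @ Rx(b) @ Ry(a)`` (radians, batched).

    The rotation-obliquity-tilt sequence used for the pelvis: the axial
    rotation is the outermost factor, so tilt and obliquity do not depend
    on the direction of walking.
    """
    c, b, a = np.broadcast_arrays(
        np.asarray(c, float), np.asarray(b, float), np.asarray(a, float)
    )
    angles = np.stack([c, b, a], axis=-1)
    return Rotation.from_euler("ZXY", angles.reshape(-1, 3)).as_matrix().reshape(
        angles.shape[:-1] + (3, 3)
    )


def euler_zxy(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`rotation_zxy`; returns ``(c, b, a)`` in radians."""
    R = np.asarray(R, dtype=float)
    shape = R.shape[:-2]
    ang = Rotation.from_matrix(R.reshape(-1, 3, 3)).as_euler("ZXY").reshape(shape + (3,))
    return ang[..., 0], ang[..., 1], ang[..., 2]


def euler_yxz(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`rotation_yxz`; returns ``(a, b, c)`` in radians."""
    R = np.asarray(R, dtype=float)
    shape = R.shape[:-2]
    ang = Rotation.from_matrix(R.reshape(-1, 3, 3)).as_euler("YXZ").reshape(shape + (3,))
    return ang[..., 0], ang[..., 1], ang[..., 2]


def relative_rotation(R_parent: np.ndarray, R_child: np.ndarray) -> np.ndarray:
    """Child orientation expressed in the parent frame: ``Rp^T @ Rc``."""
    return np.einsum("...ji,...jk->...ik", R_parent, R_child)
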