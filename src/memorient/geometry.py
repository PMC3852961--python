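"""Rigid-body pose primitives.

A membrane pose has three degrees of freedom: rotation about the x axis,
rotation about the y axis, and translation along the z axis (the membrane
normal).  Rotations are right-handed and applied as ``R_y(rot_y) @
R_x(rot_x)``; angles are degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Transform", "rotation_matrix", "apply_transform", "z_components"]


@dataclass(frozen=True)
class Transform:
    """A 3-parameter membrane pose.

    ``rot_x`` and ``rot_y`` are stored reduced to [0, 360); ``dz`` is the
    z translation in Angstroms applied after the rotation.
    """

    rot_x: float = 0.0
    rot_y: float = 0.0
    dz: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot_x", float(self.rot_x) % 360.0)
        object.__setattr__(self, "rot_y", float(self.rot_y) % 360.0)
        object.__setattr__(self, "dz", float(self.dz))
        if not (np.isfinite(self.rot_x) and np.isfinite(self.rot_y) and np.isfinite(self.dz)):
            raise ValueError("transform parameters must be finite")

    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.rot_x, self.rot_y)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rot_x, self.rot_y, self.dz)


IDENTITY = Transform(0.0, 0.0, 0.0)


def rotation_matrix(rot_x: float, rot_y: float) -> np.ndarray:
    """Right-handed ``R_y(rot_y) @ R_x(rot_x)`` for angles in degrees."""
    ax = np.deg2rad(rot_x)
    ay = np.deg2rad(rot_y)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    return ry @ rx


def apply_transform(points: np.ndarray, t: Transform) -> np.ndarray:
    """Transform an (N, 3) array of points: rotate, then translate along z."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
        out = pts @ t.rotation().T
        out[:, 2] += t.dz
        return out[0]
    out = pts @ t.rotation().T
    out[:, 2] += t.dz
    return out


def z_components(rot_x_deg, rot_y_deg) -> np.ndarray:
    """Third row of ``R_y @ R_x`` for (arrays of) angles in degrees.

    The dot product of the returned row with a point gives the rotated
    z-coordinate; shape is ``(..., 3)``.  This is the only part of the
    rotation the depth potential needs, which makes batched pose
    evaluation cheap.
    """
    ax = np.deg2rad(np.asarray(rot_x_deg, dtype=float))
    ay = np.deg2rad(np.asarray(rot_y_deg, dtype=float))
    return np.stack(
        [-np.sin(ay), np.cos(ay) * np.sin(ax), np.cos(ay) * np.cos(ax)],
        axis=-1,
    )
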