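"""Rigid-body poses, pinhole cameras and angle computations.

World units are millimetres throughout (tip errors are reported in mm).
Image coordinates are 0-based ``(column, row) = (x, y)`` with pixel centers
at integer coordinates. Rotations are stored as 3x3 matrices internally;
quaternions ``(w, x, y, z)`` are accepted at I/O boundaries and normalized
on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidPose",
    "CameraModel",
    "normalize_direction",
    "angle_between",
    "project",
    "project_points",
    "transform_point",
    "view_axis",
    "load_camera_rig",
    "save_camera_rig",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidPose:
    """A rotation + translation placing a rigid body in a parent frame.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1;
    ``translation`` is a 3-vector in millimetres. Points transform as
    ``R @ p + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("pose contains non-finite entries")
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (deviation {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.eye(3), np.zeros(3))

    @staticmethod
    def from_quat(q: np.ndarray, t: np.ndarray) -> "RigidPose":
        """Build from a ``(w, x, y, z)`` quaternion (normalized on read)."""
        q = np.asarray(q, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if n == 0:
            raise ValueError("zero quaternion")
        q = q / n
        R = Rotation.from_quat(q[[1, 2, 3, 0]]).as_matrix()  # scipy uses xyzw
        return RigidPose(R, np.asarray(t, dtype=float))

    def as_quat(self) -> np.ndarray:
        """Quaternion ``(w, x, y, z)`` with non-negative w."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # xyzw
        q = q[[3, 0, 1, 2]]
        if q[0] < 0:
            q = -q
        return q

    def compose(self, other: "RigidPose") -> "RigidPose":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        Rt = self.rotation.T
        return RigidPose(Rt, -Rt @ self.translation)

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point ``(3,)`` or a stack ``(..., 3)``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: intrinsics in pixels + world-to-camera extrinsic."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    extrinsic: RigidPose = field(default_factory=RigidPose.identity)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("image size must be at least 1x1")

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return self.extrinsic.transform(points)

    def contains(self, uv: np.ndarray) -> np.ndarray:
        """Whether pixel coordinates fall inside the image bounds."""
        uv = np.asarray(uv, dtype=float)
        u, v = uv[..., 0], uv[..., 1]
        return (u >= 0) & (u <= self.width - 1) & (v >= 0) & (v <= self.height - 1)


def normalize_direction(v: np.ndarray) -> np.ndarray:
    """Return ``v / ||v||``; raises on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero-length direction")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two directions in degrees, in [0, 180].

    Inputs need not be exactly unit length; they are normalized defensively
    and the dot product is clamped before ``arccos``.
    """
    a = normalize_direction(a)
    b = normalize_direction(b)
    d = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    return float(np.degrees(np.arccos(d)))


def transform_point(pose: RigidPose, point: np.ndarray) -> np.ndarray:
    """``R @ p + t`` for a single object-frame point."""
    return pose.transform(point)


def project_points(camera: CameraModel, points_world: np.ndarray):
    """Project world points; returns ``(uv, in_front)``.

    ``uv`` has shape ``(..., 2)``; entries with camera-frame depth Z <= 0 are
    flagged False in ``in_front`` and their ``uv`` values are not meaningful.
    """
    pc = camera.world_to_camera(points_world)
    z = pc[..., 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.fx * pc[..., 0] / z + camera.cx
        v = camera.fy * pc[..., 1] / z + camera.cy
    uv = np.stack([u, v], axis=-1)
    uv[~in_front] = np.nan
    return uv, in_front


def project(point_world: np.ndarray, camera: CameraModel):
    """Project a single world point to pixels, or ``None`` if behind camera.

    "Behind camera" (depth Z <= 0) is a value, not an error.
    """
    uv, in_front = project_points(camera, np.asarray(point_world, dtype=float))
    if not bool(in_front):
        return None
    return uv


def view_axis(camera: CameraModel) -> np.ndarray:
    """World-frame unit vector of the camera's optical (+z) axis."""
    ax = camera.extrinsic.rotation.T @ np.array([0.0, 0.0, 1.0])
    return normalize_direction(ax)


def unproject(camera: CameraModel, uv: np.ndarray, depth: float) -> np.ndarray:
    """World point on the ray through pixel ``uv`` at camera-frame depth (mm)."""
    u, v = float(uv[0]), float(uv[1])
    pc = np.array(
        [(u - camera.cx) / camera.fx * depth, (v - camera.cy) / camera.fy * depth, depth]
    )
    return camera.extrinsic.inverse().transform(pc)


# --- calibration file I/O -------------------------------------------------

def _camera_to_dict(cam: CameraModel) -> dict:
    q = cam.extrinsic.as_quat()
    return {
        "fx": cam.fx,
        "fy": cam.fy,
        "cx": cam.cx,
        "cy": cam.cy,
        "width": cam.width,
        "height": cam.height,
        "q": [float(x) for x in q],
        "t": [float(x) for x in cam.extrinsic.translation],
    }


def _camera_from_dict(d: dict) -> CameraModel:
    pose = RigidPose.from_quat(np.asarray(d["q"]), np.asarray(d["t"]))
    return CameraModel(
        fx=float(d["fx"]),
        fy=float(d["fy"]),
        cx=float(d["cx"]),
        cy=float(d["cy"]),
        width=int(d["width"]),
        height=int(d["height"]),
        extrinsic=pose,
    )


def save_camera_rig(path: str | Path, cameras: list[CameraModel]) -> None:
    """Write a rig calibration JSON (one file per rig, one entry per camera)."""
    payload = {"cameras": [_camera_to_dict(c) for c in cameras]}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_camera_rig(path: str | Path) -> list[CameraModel]:
    payload = json.loads(Path(path).read_text())
    return [_camera_from_dict(d) for d in payload["cameras"]]
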