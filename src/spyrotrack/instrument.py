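"""Object-frame geometry of the tracked instrument.

An :class:`InstrumentModel` holds the scoring keypoints (selected by
furthest-point sampling on the 3D model), the designated tip and rear points
that define the instrument axis, and a set of surface samples used for the
visibility metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import RigidPose, normalize_direction

__all__ = [
    "InstrumentModel",
    "furthest_point_sample",
    "tip_rear_world",
    "default_instrument",
    "load_instrument",
    "save_instrument",
    "instrument_from_mesh",
]


@dataclass(frozen=True)
class InstrumentModel:
    """Keypoints, tip/rear points and surface samples, all object-frame mm."""

    keypoints: np.ndarray  # (K, 3)
    tip: np.ndarray  # (3,)
    rear: np.ndarray  # (3,)
    surface_points: np.ndarray  # (S, 3)

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float).reshape(-1, 3)
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        rear = np.asarray(self.rear, dtype=float).reshape(3)
        sp = np.asarray(self.surface_points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "keypoints", kp)
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "rear", rear)
        object.__setattr__(self, "surface_points", sp)
        if kp.shape[0] < 4:
            raise ValueError("need at least 4 keypoints for pose observability")
        if np.allclose(tip, rear):
            raise ValueError("tip and rear must be distinct points")
        for arr in (kp, tip, rear, sp):
            if not np.all(np.isfinite(arr)):
                raise ValueError("instrument geometry contains non-finite points")

    @property
    def n_keypoints(self) -> int:
        return self.keypoints.shape[0]


def furthest_point_sample(
    candidates: np.ndarray, k: int, seed_index: int | None = None
) -> np.ndarray:
    """Greedy max-min Euclidean selection of ``k`` well-spread points.

    The first output row is ``candidates[seed_index]``; each subsequent point
    maximizes its distance to the already-selected set. Ties are broken by the
    lowest input index, so the result is deterministic across platforms. When
    ``seed_index`` is None it defaults to the point furthest from the centroid
    (again lowest index on ties).
    """
    pts = np.asarray(candidates, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError("not enough candidate points")
    if seed_index is None:
        centroid = pts.mean(axis=0)
        seed_index = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
    if not 0 <= seed_index < n:
        raise ValueError("seed_index out of range")

    selected = [seed_index]
    min_dist = np.linalg.norm(pts - pts[seed_index], axis=1)
    for _ in range(k - 1):
        # argmax returns the first (lowest-index) maximizer: the tie-break.
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[selected]


def tip_rear_world(pose: RigidPose, model: InstrumentModel):
    """World-frame tip, rear and the unit direction rear -> tip."""
    tip_w = pose.transform(model.tip)
    rear_w = pose.transform(model.rear)
    direction = normalize_direction(tip_w - rear_w)
    return tip_w, rear_w, direction


def default_instrument(
    n_keypoints: int = 8,
    n_surface: int = 200,
    length: float = 120.0,
    radius: float = 5.0,
    seed: int = 0,
) -> InstrumentModel:
    """Synthetic straight-shaft instrument (screwdriver-like elongation).

    A ``length`` mm shaft along +z with the tip at ``(0, 0, length)`` and the
    rear at the origin; surface samples lie on a cylinder of ``radius`` mm.
    Dimensions are an artifact choice for desk-scale experiments.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, length, size=n_surface)
    theta = rng.uniform(0.0, 2 * np.pi, size=n_surface)
    surface = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    # Keypoint candidates: rings along the shaft; FPS picks the spread subset.
    zs = np.linspace(0.0, length, 16)
    ring = np.array([[radius, 0.0], [-radius, 0.0], [0.0, radius], [0.0, -radius]])
    cand = np.array([[x, y, zz] for zz in zs for x, y in ring])
    keypoints = furthest_point_sample(cand, n_keypoints)
    return InstrumentModel(
        keypoints=keypoints,
        tip=np.array([0.0, 0.0, length]),
        rear=np.zeros(3),
        surface_points=surface,
    )


def save_instrument(path: str | Path, model: InstrumentModel) -> None:
    payload = {
        "keypoints": model.keypoints.tolist(),
        "tip": model.tip.tolist(),
        "rear": model.rear.tolist(),
        "surface_points": model.surface_points.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_instrument(path: str | Path) -> InstrumentModel:
    d = json.loads(Path(path).read_text())
    return InstrumentModel(
        keypoints=np.asarray(d["keypoints"]),
        tip=np.asarray(d["tip"]),
        rear=np.asarray(d["rear"]),
        surface_points=np.asarray(d["surface_points"]),
    )


def instrument_from_mesh(
    path: str | Path,
    tip: np.ndarray,
    rear: np.ndarray,
    n_keypoints: int = 8,
    n_surface: int = 200,
    seed: int = 0,
) -> InstrumentModel:
    """Build an instrument model from a PLY/OBJ mesh.

    Keypoints are derived by furthest-point sampling of the mesh vertices and
    surface points by uniform face-area sampling. Tip and rear must be
    supplied; a mesh does not identify them.
    """
    import trimesh

    mesh = trimesh.load(str(path), force="mesh")
    keypoints = furthest_point_sample(np.asarray(mesh.vertices, dtype=float), n_keypoints)
    surface, _ = trimesh.sample.sample_surface(mesh, n_surface, seed=seed)
    return InstrumentModel(
        keypoints=keypoints,
        tip=np.asarray(tip, dtype=float),
        rear=np.asarray(rear, dtype=float),
        surface_points=np.asarray(surface, dtype=float),
    )
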