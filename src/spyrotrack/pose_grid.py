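"""Coarse-to-fine hierarchical pose-hypothesis grids over SE(3).

The joint grid is the Cartesian product of a rotation grid and a translation
octree over an axis-aligned workspace box. Refinement keeps the ``top_k``
highest-probability cells (importance sampling guided by the learned or
analytic scores), subdivides each into ``8 x 8`` rotation/translation
children, rescores and renormalizes. Dropped mass is renormalized away, so
each level's distribution is conditional on the retained region.

Rotation grid
-------------
Rotations are parameterized by intrinsic yaw-pitch-roll Euler angles
(``Rz(a) @ Ry(b) @ Rx(g)``) with ``a in [0, 2pi)``, ``b in [-pi/2, pi/2]``,
``g in [0, 2pi)`` and partitioned into uniform angle boxes. A cell subdivides
into 8 children by halving each angle axis, so children tile their parent
exactly — which makes exhaustive refinement provably identical to brute-force
enumeration of the finest grid. The default base shape (4, 3, 6) yields 72
level-0 rotation cells. Angle boxes are not equivolumetric on SO(3); that
trade-off is documented rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import logsumexp

from .geometry import RigidPose

__all__ = [
    "Box",
    "GridSpec",
    "GridCell",
    "PoseDistribution",
    "base_grid",
    "subdivide",
    "refine",
    "normalize",
    "cell_containing",
    "estimate_distribution",
]


@dataclass(frozen=True, eq=False)
class Box:
    """Axis-aligned workspace box in world millimetres."""

    lo: np.ndarray
    hi: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Box):
            return NotImplemented
        return bool(np.array_equal(self.lo, other.lo) and np.array_equal(self.hi, other.hi))

    def __hash__(self) -> int:
        return hash((tuple(self.lo), tuple(self.hi)))

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float).reshape(3)
        hi = np.asarray(self.hi, dtype=float).reshape(3)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if np.any(hi <= lo):
            raise ValueError("degenerate workspace box")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)

    @property
    def size(self) -> np.ndarray:
        return self.hi - self.lo


@dataclass(frozen=True)
class GridSpec:
    """Granularity of the hierarchical SE(3) grid.

    ``rotation_base_shape`` is the level-0 partition of (yaw, pitch, roll);
    its product is the level-0 rotation-cell count (default 4*3*6 = 72).
    Each rotation cell branches into 8 children per level and each
    translation axis halves per level (8 translation children).
    """

    rotation_base_shape: tuple[int, int, int] = (4, 3, 6)
    position_base_shape: tuple[int, int, int] = (4, 4, 4)
    max_level: int = 3
    top_k: int | None = 512

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.rotation_base_shape):
            raise ValueError("rotation_base_shape entries must be >= 1")
        if any(c < 1 for c in self.position_base_shape):
            raise ValueError("position_base_shape entries must be >= 1")
        if self.max_level < 0:
            raise ValueError("max_level must be >= 0")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 (or None for exhaustive)")

    @property
    def rotation_base_count(self) -> int:
        return int(np.prod(self.rotation_base_shape))

    @property
    def rotation_branching(self) -> int:
        return 8

    @property
    def position_branching(self) -> int:
        return 2  # per axis

    def rotation_shape(self, level: int) -> tuple[int, int, int]:
        return tuple(int(c) * 2**level for c in self.rotation_base_shape)

    def position_shape(self, level: int) -> tuple[int, int, int]:
        return tuple(int(c) * 2**level for c in self.position_base_shape)

    def position_cell_size(self, workspace: Box, level: int) -> np.ndarray:
        return workspace.size / np.asarray(self.position_shape(level), dtype=float)

    def position_cell_diagonal(self, workspace: Box, level: int) -> float:
        return float(np.linalg.norm(self.position_cell_size(workspace, level)))

    def rotation_cell_angular_radius(self, level: int, n_yaw_samples: int = 2) -> float:
        """Max geodesic distance (degrees) from a cell center to its corners.

        The distance is invariant to the yaw of the cell (a global rotation
        premultiplies both center and corners), so only pitch and roll rows
        need to be scanned; a couple of yaw rows are included defensively.
        """
        na, nb, nc = self.rotation_shape(level)
        widths = _ROT_RANGES[:, 1] - _ROT_RANGES[:, 0]
        da, db, dg = widths / np.array([na, nb, nc])
        i_idx = np.arange(min(na, n_yaw_samples))
        j_idx = np.arange(nb)
        k_idx = np.arange(nc)
        ii, jj, kk = np.meshgrid(i_idx, j_idx, k_idx, indexing="ij")
        centers = np.stack(
            [
                _ROT_RANGES[0, 0] + (ii.ravel() + 0.5) * da,
                _ROT_RANGES[1, 0] + (jj.ravel() + 0.5) * db,
                _ROT_RANGES[2, 0] + (kk.ravel() + 0.5) * dg,
            ],
            axis=1,
        )
        rad = 0.0
        Rc = Rotation.from_euler("ZYX", centers)
        for sa in (-0.5, 0.5):
            for sb in (-0.5, 0.5):
                for sg in (-0.5, 0.5):
                    corner = centers + np.array([sa * da, sb * db, sg * dg])
                    Rk = Rotation.from_euler("ZYX", corner)
                    ang = (Rc.inv() * Rk).magnitude()
                    rad = max(rad, float(ang.max()))
        return float(np.degrees(rad))


# (yaw, pitch, roll) ranges of the Euler-box parameterization
_ROT_RANGES = np.array([[0.0, 2 * np.pi], [-np.pi / 2, np.pi / 2], [0.0, 2 * np.pi]])


@dataclass(frozen=True)
class GridCell:
    """One pose hypothesis: a cell of the hierarchical grid at some level."""

    level: int
    rot_index: int
    pos_index: tuple[int, int, int]
    pose: RigidPose
    log_score: float = 0.0
    prob: float | None = None


@dataclass
class PoseDistribution:
    """Scored pose hypotheses at a single grid level (vectorized storage).

    ``rot_index`` is the flat index into the level's rotation grid and
    ``pos_index`` the 3-integer translation-cell index. ``prob`` is None
    until :func:`normalize` is called. Cells are kept sorted by cell id
    (``rot_index`` major, flattened ``pos_index`` minor) so that stable
    sorts break probability ties toward the lower cell id.
    """

    level: int
    spec: GridSpec
    workspace: Box
    rot_index: np.ndarray  # (N,) int64
    pos_index: np.ndarray  # (N, 3) int64
    log_score: np.ndarray  # (N,) float
    prob: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.rot_index.shape[0])

    @property
    def normalized(self) -> bool:
        return self.prob is not None

    # --- geometry of the representatives ---------------------------------

    def rotations(self) -> np.ndarray:
        """(N, 3, 3) cell-center rotation matrices."""
        return _rotations_from_index(self.spec, self.level, self.rot_index)

    def translations(self) -> np.ndarray:
        """(N, 3) cell-center translations (mm)."""
        return _translations_from_index(
            self.spec, self.level, self.pos_index, self.workspace
        )

    def cell_ids(self) -> np.ndarray:
        return _cell_ids(self.spec, self.level, self.rot_index, self.pos_index)

    def cell(self, i: int) -> GridCell:
        R = _rotations_from_index(self.spec, self.level, self.rot_index[i : i + 1])[0]
        t = _translations_from_index(
            self.spec, self.level, self.pos_index[i : i + 1], self.workspace
        )[0]
        return GridCell(
            level=self.level,
            rot_index=int(self.rot_index[i]),
            pos_index=tuple(int(x) for x in self.pos_index[i]),
            pose=RigidPose(R, t),
            log_score=float(self.log_score[i]),
            prob=None if self.prob is None else float(self.prob[i]),
        )

    def argmax(self) -> int:
        """Index of the highest-probability cell (ties -> lower cell id)."""
        if self.prob is None:
            raise ValueError("distribution is not normalized")
        return int(np.argsort(-self.prob, kind="stable")[0])

    def top(self, n: int) -> np.ndarray:
        """Indices of the top-n cells by probability (ties -> lower cell id)."""
        if self.prob is None:
            raise ValueError("distribution is not normalized")
        return np.argsort(-self.prob, kind="stable")[:n]

    def to_dataframe(self):
        """Distribution dump with quaternion pose representatives."""
        import pandas as pd

        R = Rotation.from_matrix(self.rotations()).as_quat()  # xyzw
        q = R[:, [3, 0, 1, 2]]
        q[q[:, 0] < 0] *= -1
        t = self.translations()
        return pd.DataFrame(
            {
                "level": self.level,
                "rot_index": self.rot_index,
                "pos_x": self.pos_index[:, 0],
                "pos_y": self.pos_index[:, 1],
                "pos_z": self.pos_index[:, 2],
                "qw": q[:, 0],
                "qx": q[:, 1],
                "qy": q[:, 2],
                "qz": q[:, 3],
                "tx": t[:, 0],
                "ty": t[:, 1],
                "tz": t[:, 2],
                "log_score": self.log_score,
                "prob": np.nan if self.prob is None else self.prob,
            }
        )


# --- index <-> representative maps ---------------------------------------

def _rotations_from_index(spec: GridSpec, level: int, rot_index: np.ndarray) -> np.ndarray:
    na, nb, nc = spec.rotation_shape(level)
    idx = np.asarray(rot_index, dtype=np.int64)
    i = idx // (nb * nc)
    j = (idx // nc) % nb
    k = idx % nc
    widths = (_ROT_RANGES[:, 1] - _ROT_RANGES[:, 0]) / np.array([na, nb, nc])
    ang = np.stack(
        [
            _ROT_RANGES[0, 0] + (i + 0.5) * widths[0],
            _ROT_RANGES[1, 0] + (j + 0.5) * widths[1],
            _ROT_RANGES[2, 0] + (k + 0.5) * widths[2],
        ],
        axis=1,
    )
    return Rotation.from_euler("ZYX", ang).as_matrix()


def _translations_from_index(
    spec: GridSpec, level: int, pos_index: np.ndarray, workspace: Box
) -> np.ndarray:
    shape = np.asarray(spec.position_shape(level), dtype=float)
    cell = workspace.size / shape
    return workspace.lo + (np.asarray(pos_index, dtype=float) + 0.5) * cell


def _cell_ids(spec: GridSpec, level: int, rot_index: np.ndarray, pos_index: np.ndarray) -> np.ndarray:
    nx, ny, nz = spec.position_shape(level)
    flat_pos = (pos_index[:, 0] * ny + pos_index[:, 1]) * nz + pos_index[:, 2]
    return rot_index.astype(np.int64) * (nx * ny * nz) + flat_pos


def _sort_canonical(dist: PoseDistribution) -> PoseDistribution:
    order = np.argsort(dist.cell_ids(), kind="stable")
    dist.rot_index = dist.rot_index[order]
    dist.pos_index = dist.pos_index[order]
    dist.log_score = dist.log_score[order]
    if dist.prob is not None:
        dist.prob = dist.prob[order]
    return dist


# --- operations -----------------------------------------------------------

def base_grid(spec: GridSpec, workspace: Box) -> PoseDistribution:
    """Level-0 grid: Cartesian product of rotation and translation cells.

    Every cell starts with ``log_score = 0`` (uniform before scoring).
    """
    n_rot = spec.rotation_base_count
    nx, ny, nz = spec.position_base_shape
    pos = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    n_pos = pos.shape[0]
    rot_index = np.repeat(np.arange(n_rot, dtype=np.int64), n_pos)
    pos_index = np.tile(pos, (n_rot, 1)).astype(np.int64)
    dist = PoseDistribution(
        level=0,
        spec=spec,
        workspace=workspace,
        rot_index=rot_index,
        pos_index=pos_index,
        log_score=np.zeros(n_rot * n_pos),
    )
    return _sort_canonical(dist)


def _subdivide_indices(rot_index: np.ndarray, pos_index: np.ndarray, log_score: np.ndarray):
    """Vectorized 64-way subdivision (8 rotation x 8 translation children)."""
    n = rot_index.shape[0]
    # rotation children: each angle axis doubles; child offsets in {0,1}^3
    off = np.stack(
        np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij"), axis=-1
    ).reshape(-1, 3)  # (8, 3)

    def child_rot(parent_flat: np.ndarray, na: int, nb: int, nc: int) -> np.ndarray:
        i = parent_flat // (nb * nc)
        j = (parent_flat // nc) % nb
        k = parent_flat % nc
        ci = 2 * i[:, None] + off[None, :, 0]
        cj = 2 * j[:, None] + off[None, :, 1]
        ck = 2 * k[:, None] + off[None, :, 2]
        return (ci * (2 * nb) + cj) * (2 * nc) + ck  # (n, 8)

    return off, child_rot


def subdivide(cell: GridCell, spec: GridSpec, workspace: Box) -> list[GridCell]:
    """All 64 children of one cell at the next level.

    Children's translation boxes tile the parent's box exactly and their
    rotation angle-boxes tile the parent's; each child inherits the parent's
    ``log_score`` until rescored.
    """
    if cell.level >= spec.max_level:
        raise ValueError("finest level reached")
    parent = PoseDistribution(
        level=cell.level,
        spec=spec,
        workspace=workspace,
        rot_index=np.array([cell.rot_index], dtype=np.int64),
        pos_index=np.array([cell.pos_index], dtype=np.int64),
        log_score=np.array([cell.log_score]),
    )
    child = _subdivide_distribution(parent)
    return [child.cell(i) for i in range(len(child))]


def _subdivide_distribution(dist: PoseDistribution) -> PoseDistribution:
    spec = dist.spec
    na, nb, nc = spec.rotation_shape(dist.level)
    off, child_rot = _subdivide_indices(dist.rot_index, dist.pos_index, dist.log_score)
    rot_children = child_rot(dist.rot_index, na, nb, nc)  # (n, 8)
    pos_children = 2 * dist.pos_index[:, None, :] + off[None, :, :]  # (n, 8, 3)
    n = len(dist)
    # full product: (n, 8 rot, 8 pos)
    rot_full = np.repeat(rot_children[:, :, None], 8, axis=2).reshape(n, 64)
    pos_full = np.repeat(pos_children[:, None, :, :], 8, axis=1).reshape(n, 64, 3)
    score_full = np.repeat(dist.log_score[:, None], 64, axis=1)
    child = PoseDistribution(
        level=dist.level + 1,
        spec=spec,
        workspace=dist.workspace,
        rot_index=rot_full.reshape(-1),
        pos_index=pos_full.reshape(-1, 3),
        log_score=score_full.reshape(-1),
    )
    return _sort_canonical(child)


def normalize(dist: PoseDistribution) -> PoseDistribution:
    """Softmax over log-scores: ``prob_i = exp(s_i - logsumexp(s))``."""
    if len(dist) == 0:
        raise ValueError("cannot normalize an empty distribution")
    if not np.all(np.isfinite(dist.log_score)):
        bad = int(np.flatnonzero(~np.isfinite(dist.log_score))[0])
        raise ValueError(
            f"non-finite log-score at cell (level={dist.level}, "
            f"rot_index={int(dist.rot_index[bad])}, "
            f"pos_index={tuple(int(x) for x in dist.pos_index[bad])})"
        )
    lse = logsumexp(dist.log_score)
    return replace(dist, prob=np.exp(dist.log_score - lse))


def cell_containing(
    spec: GridSpec, level: int, workspace: Box, pose: RigidPose
) -> tuple[int, tuple[int, int, int]]:
    """``(rot_index, pos_index)`` of the cell whose box contains ``pose``.

    The rotation index comes from the pose's yaw-pitch-roll angles mapped
    into the Euler-box partition; the translation index from the octree
    cell containing the translation (clamped to the workspace).
    """
    ang = Rotation.from_matrix(pose.rotation).as_euler("ZYX")
    ang = np.array([ang[0] % (2 * np.pi), ang[1], ang[2] % (2 * np.pi)])
    na, nb, nc = spec.rotation_shape(level)
    widths = (_ROT_RANGES[:, 1] - _ROT_RANGES[:, 0]) / np.array([na, nb, nc])
    ijk = np.floor((ang - _ROT_RANGES[:, 0]) / widths).astype(int)
    ijk = np.clip(ijk, 0, np.array([na, nb, nc]) - 1)
    rot_index = int((ijk[0] * nb + ijk[1]) * nc + ijk[2])
    shape = np.asarray(spec.position_shape(level))
    cell = workspace.size / shape
    pidx = np.floor((pose.translation - workspace.lo) / cell).astype(int)
    pidx = np.clip(pidx, 0, shape - 1)
    return rot_index, tuple(int(x) for x in pidx)


Scorer = Callable[[PoseDistribution], np.ndarray]


def _apply_scorer(dist: PoseDistribution, scorer: Scorer) -> PoseDistribution:
    scores = np.asarray(scorer(dist), dtype=float).reshape(-1)
    if scores.shape[0] != len(dist):
        raise ValueError("scorer returned wrong number of scores")
    if not np.all(np.isfinite(scores)):
        bad = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise ValueError(
            f"scorer returned a non-finite value at cell (level={dist.level}, "
            f"rot_index={int(dist.rot_index[bad])}, "
            f"pos_index={tuple(int(x) for x in dist.pos_index[bad])})"
        )
    dist.log_score = scores
    dist.prob = None
    return dist


def refine(dist: PoseDistribution, scorer: Scorer, spec: GridSpec) -> PoseDistribution:
    """One importance-sampling refinement step.

    Keeps the ``top_k`` cells by probability (ties to the lower cell id),
    subdivides each into its 64 children, rescores all children and
    normalizes. Cells not expanded are dropped, so the refined distribution
    is conditional on the retained region.
    """
    if not dist.normalized:
        raise ValueError("refine requires a scored, normalized distribution")
    if dist.level >= spec.max_level:
        raise ValueError("finest level reached")
    k = len(dist) if spec.top_k is None else min(spec.top_k, len(dist))
    keep = dist.top(k)
    kept = PoseDistribution(
        level=dist.level,
        spec=spec,
        workspace=dist.workspace,
        rot_index=dist.rot_index[keep],
        pos_index=dist.pos_index[keep],
        log_score=dist.log_score[keep],
    )
    _sort_canonical(kept)
    children = _subdivide_distribution(kept)
    children = _apply_scorer(children, scorer)
    return normalize(children)


def estimate_distribution(
    scorer: Scorer, spec: GridSpec, workspace: Box
) -> PoseDistribution:
    """Full coarse-to-fine pass: score level 0, then refine to ``max_level``."""
    dist = base_grid(spec, workspace)
    dist = normalize(_apply_scorer(dist, scorer))
    for _ in range(spec.max_level):
        dist = refine(dist, scorer, spec)
    return dist
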