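"""Multi-view fusion and point-estimation strategies.

Early fusion shares one world-frame hypothesis grid across all camera views
and sums per-view log-scores inside the coarse-to-fine refinement (sensor
fusion inside the estimator). Late fusion runs the estimator per view and
combines the resulting point estimates afterwards.

Three strategies turn a pose distribution into the final tip position and
instrument direction:

* max probability — the argmax cell's pose;
* weighted averages — probability-weighted mean of the top-n cells' tip and
  rear points;
* grid-based — each top-n candidate tip spawns a cuboid stretched along the
  depth axis (depth errors dominate, so ``dz >= dx, dy``); cuboids are
  rasterized onto a uniform accumulation grid, overlapping probabilities
  add, and the highest-total cell wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CameraModel, normalize_direction
from .instrument import InstrumentModel
from .pose_grid import Box, GridSpec, PoseDistribution, estimate_distribution

__all__ = [
    "PointEstimate",
    "GridBasedConfig",
    "fuse_early",
    "fuse_late",
    "estimate_max_prob",
    "estimate_weighted_avg",
    "estimate_grid_based",
]


@dataclass(frozen=True)
class PointEstimate:
    """Final tip/rear positions (mm, world), axis direction and weight."""

    tip: np.ndarray
    rear: np.ndarray
    direction: np.ndarray
    prob: float

    def __post_init__(self) -> None:
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        rear = np.asarray(self.rear, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3)
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "rear", rear)
        object.__setattr__(self, "direction", direction)
        expected = normalize_direction(tip - rear)
        if np.linalg.norm(expected - direction) > 1e-8:
            raise ValueError("direction must equal normalize(tip - rear)")


@dataclass(frozen=True)
class GridBasedConfig:
    """Accumulation-grid estimator parameters (all mm)."""

    n: int = 64
    dx: float = 2.0
    dy: float = 2.0
    dz: float = 8.0
    cell_size: float = 1.0
    depth_axis: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("dx, dy must be positive")
        if self.dz < max(self.dx, self.dy):
            raise ValueError("dz must be at least as large as dx and dy")
        if self.cell_size > min(self.dx, self.dy):
            raise ValueError("cell_size must not exceed min(dx, dy)")
        if self.depth_axis is None:
            raise ValueError("depth_axis must be set (degenerate depth axis)")
        ax = np.asarray(self.depth_axis, dtype=float).reshape(3)
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise ValueError("degenerate depth_axis")
        object.__setattr__(self, "depth_axis", ax / n)


# --- fusion ---------------------------------------------------------------

def fuse_early(view_scorer, views, spec: GridSpec, workspace: Box) -> PoseDistribution:
    """Shared-grid multi-view estimation.

    ``view_scorer(observation, camera)`` must return a per-view scorer over a
    :class:`PoseDistribution`; the fused log-score of each cell is the sum of
    per-view log-scores, and refinement selects the ``top_k`` cells by the
    fused probabilities. With a single view this reduces exactly to the
    single-view pipeline.
    """
    if len(views) < 1:
        raise ValueError("fuse_early requires at least one view")
    scorers = [view_scorer(obs, cam) for obs, cam in views]

    def fused(dist: PoseDistribution) -> np.ndarray:
        total = np.zeros(len(dist))
        for s in scorers:
            total += np.asarray(s(dist), dtype=float)
        return total

    return estimate_distribution(fused, spec, workspace)


def fuse_late(
    per_view_estimates: list[tuple[PointEstimate, CameraModel]]
) -> PointEstimate:
    """Combine per-view point estimates after estimation.

    Tip and rear points are averaged with weights proportional to each
    view's estimate probability (renormalized; uniform if all are zero) and
    the direction is recomputed from the combined endpoints. The combined
    ``prob`` is the mean of the per-view probabilities.
    """
    if len(per_view_estimates) < 1:
        raise ValueError("fuse_late requires at least one estimate")
    ests = [e for e, _cam in per_view_estimates]
    w = np.array([max(e.prob, 0.0) for e in ests], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    tip = sum(wi * e.tip for wi, e in zip(w, ests))
    rear = sum(wi * e.rear for wi, e in zip(w, ests))
    return PointEstimate(
        tip=tip,
        rear=rear,
        direction=normalize_direction(tip - rear),
        prob=float(np.mean([e.prob for e in ests])),
    )


# --- point estimators -----------------------------------------------------

def _tips_rears(dist: PoseDistribution, model: InstrumentModel, idx: np.ndarray):
    R = dist.rotations()[idx]
    t = dist.translations()[idx]
    tips = np.einsum("nij,j->ni", R, model.tip) + t
    rears = np.einsum("nij,j->ni", R, model.rear) + t
    return tips, rears


def estimate_max_prob(dist: PoseDistribution, model: InstrumentModel) -> PointEstimate:
    """The argmax-probability cell's pose (ties to the lower cell id)."""
    if len(dist) == 0:
        raise ValueError("empty distribution")
    if not dist.normalized:
        raise ValueError("distribution must be normalized")
    i = dist.argmax()
    tips, rears = _tips_rears(dist, model, np.array([i]))
    return PointEstimate(
        tip=tips[0],
        rear=rears[0],
        direction=normalize_direction(tips[0] - rears[0]),
        prob=float(dist.prob[i]),
    )


def estimate_weighted_avg(
    dist: PoseDistribution, model: InstrumentModel, n: int
) -> PointEstimate:
    """Probability-weighted average of the top-n cells' tip and rear points.

    The reported ``prob`` is the total (pre-renormalization) probability of
    the selected cells. ``n`` exceeding the cell count is clamped with a
    warning; ``n = 1`` coincides with :func:`estimate_max_prob`.
    """
    if len(dist) == 0:
        raise ValueError("empty distribution")
    if not dist.normalized:
        raise ValueError("distribution must be normalized")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(dist):
        warnings.warn(
            f"requested top-{n} but distribution has {len(dist)} cells; clamping",
            stacklevel=2,
        )
        n = len(dist)
    idx = dist.top(n)
    w = dist.prob[idx]
    total = float(w.sum())
    wn = w / total if total > 0 else np.full(n, 1.0 / n)
    tips, rears = _tips_rears(dist, model, idx)
    tip = wn @ tips
    rear = wn @ rears
    return PointEstimate(
        tip=tip, rear=rear, direction=normalize_direction(tip - rear), prob=total
    )


def _depth_frame(depth_axis: np.ndarray) -> np.ndarray:
    """Orthonormal basis ``[u, v, w]`` (columns) with w = depth axis."""
    w = normalize_direction(depth_axis)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(w)))] = 1.0
    u = normalize_direction(np.cross(helper, w))
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def estimate_grid_based(
    dist: PoseDistribution, model: InstrumentModel, cfg: GridBasedConfig
) -> PointEstimate:
    """Cuboid-accumulation estimate of the tip position.

    Each of the top-n candidates paints its probability into every
    accumulation cell whose center lies within a cuboid centered at the
    candidate tip, with half-extents (dx, dy) in the plane perpendicular to
    the depth axis and dz along it ("combine" = add). The reported tip is
    the center of the highest-total cell; among equal-total cells the one
    nearest the probability-weighted mean tip wins, remaining ties broken by
    lexicographic cell index. The rear point comes from the highest-
    probability candidate covering the winning cell, and the direction is
    recomputed from the reported tip and that rear.
    """
    if len(dist) == 0:
        raise ValueError("empty distribution")
    if not dist.normalized:
        raise ValueError("distribution must be normalized")
    n = min(cfg.n, len(dist))
    idx = dist.top(n)
    probs = dist.prob[idx]
    tips, rears = _tips_rears(dist, model, idx)

    B = _depth_frame(cfg.depth_axis)  # world = B @ local
    tips_local = tips @ B  # (n, 3) in (u, v, depth) coordinates
    half = np.array([cfg.dx, cfg.dy, cfg.dz])
    cs = cfg.cell_size

    origin = np.floor((tips_local - half).min(axis=0) / cs) * cs
    extent = (tips_local + half).max(axis=0)
    shape = np.maximum(np.ceil((extent - origin) / cs).astype(int) + 1, 1)
    acc = np.zeros(shape)
    cover: list[tuple[tuple[slice, slice, slice], int]] = []
    for j in range(n):
        lo = tips_local[j] - half
        hi = tips_local[j] + half
        # cell centers sit at origin + (i + 0.5) * cs; covered iff center in [lo, hi]
        i_lo = np.ceil((lo - origin) / cs - 0.5).astype(int)
        i_hi = np.floor((hi - origin) / cs - 0.5).astype(int)
        i_lo = np.maximum(i_lo, 0)
        i_hi = np.minimum(i_hi, shape - 1)
        if np.any(i_hi < i_lo):
            continue
        sl = tuple(slice(a, b + 1) for a, b in zip(i_lo, i_hi))
        acc[sl] += probs[j]
        cover.append((sl, j))

    best_val = acc.max()
    tie_cells = np.argwhere(acc == best_val)
    if tie_cells.shape[0] > 1:
        mean_tip = (probs / probs.sum()) @ tips_local if probs.sum() > 0 else tips_local.mean(axis=0)
        centers = origin + (tie_cells + 0.5) * cs
        d2 = np.sum((centers - mean_tip) ** 2, axis=1)
        best_d = d2.min()
        near = tie_cells[d2 <= best_d + 1e-12]
        order = np.lexsort((near[:, 2], near[:, 1], near[:, 0]))
        win = near[order[0]]
    else:
        win = tie_cells[0]
    win_t = tuple(int(x) for x in win)

    # highest-probability candidate whose cuboid covers the winning cell
    best_j = None
    for sl, j in cover:
        if all(s.start <= w_i < s.stop for s, w_i in zip(sl, win_t)):
            if best_j is None or probs[j] > probs[best_j]:
                best_j = j
    if best_j is None:  # cannot happen: the max cell was painted by someone
        best_j = 0

    tip_local = origin + (np.asarray(win_t) + 0.5) * cs
    tip_world = B @ tip_local
    rear = rears[best_j]
    return PointEstimate(
        tip=tip_world,
        rear=rear,
        direction=normalize_direction(tip_world - rear),
        prob=float(best_val),
    )
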