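"""Pose-hypothesis scoring backends.

Two backends produce unnormalized log-likelihoods for grid cells:

* ``analytic`` — a deterministic reprojection scorer over observed 2D
  keypoints, enabling desk-scale operation of the full pipeline without a
  trained network;
* ``learned`` — bilinearly interpolated per-keypoint features from a feature
  extractor, concatenated per view and mapped to a scalar score by an MLP
  trained with the InfoNCE loss (true-pose cell positive vs. sampled
  negative cells).

The multi-view contract is early fusion: the fused log-score of a cell is
the sum of its per-view log-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import nn
from .geometry import CameraModel
from .instrument import InstrumentModel
from .pose_grid import GridCell, PoseDistribution

__all__ = [
    "KeypointObservation",
    "FeatureMap",
    "ScorerConfig",
    "BEHIND_CAMERA_PENALTY",
    "analytic_score",
    "analytic_scorer",
    "interpolate_features",
    "MLP",
    "mlp_score",
    "mlp_scorer",
    "infonce_loss",
]

BEHIND_CAMERA_PENALTY = -50.0  # finite so normalization never hits -inf


@dataclass(frozen=True)
class KeypointObservation:
    """Observed 2D keypoints in one camera view.

    ``uv`` is (K, 2) pixels; ``valid`` flags keypoints that are observed
    (occluded or behind-camera keypoints are invalid and skipped).
    """

    uv: np.ndarray
    valid: np.ndarray
    noise_scale: float = 0.0

    def __post_init__(self) -> None:
        uv = np.asarray(self.uv, dtype=float).reshape(-1, 2)
        valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        object.__setattr__(self, "uv", uv)
        object.__setattr__(self, "valid", valid)
        if uv.shape[0] != valid.shape[0]:
            raise ValueError("uv and valid lengths differ")
        if not np.all(np.isfinite(uv[valid])):
            raise ValueError("valid keypoint positions must be finite")


@dataclass(frozen=True)
class FeatureMap:
    """Dense per-pixel features for one view, shape (H, W, C)."""

    values: np.ndarray
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("feature map must be (H, W, C)")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ScorerConfig:
    backend: str = "analytic"  # {analytic | learned}
    analytic_sigma: float = 2.0  # px
    analytic_cell_aware: bool = False  # temper sigma by projected cell radius
    mlp_hidden: tuple[int, ...] = (64, 64)
    negatives_per_positive: int = 255

    def __post_init__(self) -> None:
        if self.analytic_sigma <= 0:
            raise ValueError("analytic_sigma must be positive")
        if self.backend not in ("analytic", "learned"):
            raise ValueError(f"unknown backend {self.backend!r}")


# --- analytic backend -----------------------------------------------------

def _check_observable(views) -> None:
    if not any(np.any(obs.valid) for obs, _cam in views):
        raise ValueError("unobservable pose: zero valid keypoints in every view")


def _analytic_scores_vec(
    rotations: np.ndarray,
    translations: np.ndarray,
    model: InstrumentModel,
    views,
    sigma: float,
    cell_radius: float = 0.0,
) -> np.ndarray:
    """Log-scores for N pose hypotheses; vectorized over cells.

    When ``cell_radius`` (mm) is positive, the pixel noise scale for each
    hypothesis is inflated by the projection of that world-space radius at
    the hypothesis depth, ``sigma_eff^2 = sigma^2 + (f * r / z)^2``, with the
    matching Gaussian normalization term. This approximates integrating the
    likelihood over the cell instead of evaluating it at the center point.
    """
    kp = model.keypoints  # (K, 3)
    total = np.zeros(rotations.shape[0])
    for obs, cam in views:
        if not np.any(obs.valid):
            continue  # all-invalid view contributes nothing
        idx = np.flatnonzero(obs.valid)
        world = np.einsum("nij,kj->nki", rotations, kp[idx]) + translations[:, None, :]
        pc = world @ cam.extrinsic.rotation.T + cam.extrinsic.translation
        z = pc[..., 2]
        in_front = z > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = cam.fx * pc[..., 0] / z + cam.cx
            v = cam.fy * pc[..., 1] / z + cam.cy
        du = u - obs.uv[idx, 0]
        dv = v - obs.uv[idx, 1]
        if cell_radius > 0.0:
            zc = (translations @ cam.extrinsic.rotation.T
                  + cam.extrinsic.translation)[:, 2]
            zc = np.where(zc > 1e-9, zc, np.inf)
            f = 0.5 * (cam.fx + cam.fy)
            var = sigma * sigma + (f * cell_radius / zc) ** 2  # (N,)
            sq = (du * du + dv * dv) / (2.0 * var[:, None])
            sq = sq + 0.5 * np.log(var / (sigma * sigma))[:, None]
        else:
            sq = (du * du + dv * dv) / (2.0 * sigma * sigma)
        per_kp = np.where(in_front, -sq, BEHIND_CAMERA_PENALTY)
        total += per_kp.sum(axis=1)
    return total


def analytic_score(
    cell: GridCell,
    model: InstrumentModel,
    views: list[tuple[KeypointObservation, CameraModel]],
    sigma: float = 2.0,
) -> float:
    """Reprojection log-score of one cell: sum over views and valid keypoints
    of ``-||projected - observed||^2 / (2 sigma^2)``; keypoints projecting
    behind a camera contribute a fixed ``-50`` penalty."""
    _check_observable(views)
    R = cell.pose.rotation[None]
    t = cell.pose.translation[None]
    return float(_analytic_scores_vec(R, t, model, views, sigma)[0])


def analytic_scorer(
    model: InstrumentModel,
    views: list[tuple[KeypointObservation, CameraModel]],
    sigma: float = 2.0,
    cell_aware: bool = False,
):
    """Vectorized scorer over a :class:`PoseDistribution` (early fusion).

    With ``cell_aware=True`` the noise scale is tempered per grid level: the
    world-space cell radius (translation half-diagonal plus the keypoint arm
    through the rotation-cell angular radius) is projected to pixels at each
    hypothesis depth and added in quadrature to ``sigma``. Coarse levels are
    then ranked by a smoothed likelihood that approximates the mass of the
    cell rather than its center-point density, which keeps hierarchical
    pruning reliable when many fused views make the likelihood much sharper
    than a coarse cell. At fine levels the correction vanishes.
    """
    _check_observable(views)
    arm = float(np.max(np.linalg.norm(model.keypoints, axis=1))) if cell_aware else 0.0

    def scorer(dist: PoseDistribution) -> np.ndarray:
        radius = 0.0
        if cell_aware:
            half_diag = 0.5 * dist.spec.position_cell_diagonal(
                dist.workspace, dist.level
            )
            # O(1) upper bound on the rotation-cell angular radius: half the
            # sum of the Euler cell widths (rotation triangle inequality).
            widths = np.array([2 * np.pi, np.pi, 2 * np.pi])
            ang = min(
                0.5 * float(np.sum(widths / dist.spec.rotation_shape(dist.level))),
                np.pi / 2,
            )
            radius = half_diag + arm * np.sin(ang)
        return _analytic_scores_vec(
            dist.rotations(), dist.translations(), model, views, sigma,
            cell_radius=radius,
        )

    return scorer


# --- learned backend ------------------------------------------------------

def interpolate_features(fmap: FeatureMap, points: np.ndarray):
    """Bilinear interpolation at subpixel positions.

    Returns ``(features, inside)``: points outside the image yield zero
    vectors and are flagged ``inside=False``.
    """
    vals = fmap.values
    H, W, C = vals.shape
    pts = np.asarray(points, dtype=float)
    out_shape = pts.shape[:-1]
    pts = pts.reshape(-1, 2)
    u, v = pts[:, 0], pts[:, 1]
    finite = np.isfinite(u) & np.isfinite(v)
    inside = finite & (u >= 0) & (u <= W - 1) & (v >= 0) & (v <= H - 1)
    u = np.where(inside, u, 0.0)
    v = np.where(inside, v, 0.0)
    u0 = np.floor(u).astype(int)
    v0 = np.floor(v).astype(int)
    u1 = np.minimum(u0 + 1, W - 1)
    v1 = np.minimum(v0 + 1, H - 1)
    fu = (u - u0)[:, None]
    fv = (v - v0)[:, None]
    out = (
        vals[v0, u0] * (1 - fu) * (1 - fv)
        + vals[v0, u1] * fu * (1 - fv)
        + vals[v1, u0] * (1 - fu) * fv
        + vals[v1, u1] * fu * fv
    )
    out[~inside] = 0.0
    return out.reshape(*out_shape, C), inside.reshape(out_shape)


class MLP:
    """Small fully connected scorer: ReLU hidden layers, scalar output."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...] = (64, 64),
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        dims = [in_dim, *hidden, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for a, b in zip(dims[:-1], dims[1:]):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            self.biases.append(np.zeros(b))

    @property
    def in_dim(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, D) -> (N,) scores, pure numpy."""
        h = np.asarray(x, dtype=float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[:, 0]

    def forward_t(self, x: nn.Tensor, params: list[nn.Tensor]) -> nn.Tensor:
        """Autodiff forward using Tensor-wrapped parameters (for training)."""
        n_layers = len(self.weights)
        h = x
        for i in range(n_layers - 1):
            h = h.matmul(params[2 * i]) + params[2 * i + 1]
            h = h.relu()
        return h.matmul(params[-2]) + params[-1]

    def tensor_params(self) -> list[nn.Tensor]:
        out = []
        for W, b in zip(self.weights, self.biases):
            tw = nn.Tensor(W, requires_grad=True)
            tb = nn.Tensor(b, requires_grad=True)
            tw.data = W  # share storage so optimizer steps update the MLP
            tb.data = b
            out.extend([tw, tb])
        return out

    def named_params(self, prefix: str = "mlp") -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{prefix}.w{i}"] = W
            out[f"{prefix}.b{i}"] = b
        return out

    def load_named(self, named: dict[str, np.ndarray], prefix: str = "mlp") -> None:
        for i in range(len(self.weights)):
            self.weights[i] = np.asarray(named[f"{prefix}.w{i}"], dtype=float)
            self.biases[i] = np.asarray(named[f"{prefix}.b{i}"], dtype=float)


def _project_keypoints(rotations, translations, model, cam):
    world = np.einsum("nij,kj->nki", rotations, model.keypoints) + translations[:, None, :]
    pc = world @ cam.extrinsic.rotation.T + cam.extrinsic.translation
    z = pc[..., 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cam.fx * pc[..., 0] / z + cam.cx
        v = cam.fy * pc[..., 1] / z + cam.cy
    uv = np.stack([u, v], axis=-1)
    uv[~in_front] = np.nan
    return uv, in_front


def _mlp_scores_vec(rotations, translations, model, fmap_views, mlp) -> np.ndarray:
    n = rotations.shape[0]
    K = model.n_keypoints
    total = np.zeros(n)
    for fmap, cam in fmap_views:
        uv, _ = _project_keypoints(rotations, translations, model, cam)
        feats, _ = interpolate_features(fmap, uv)  # (N, K, C)
        total += mlp.forward(feats.reshape(n, K * feats.shape[-1]))
    return total


def mlp_score(
    cell: GridCell,
    model: InstrumentModel,
    fmap_views: list[tuple[FeatureMap, CameraModel]],
    mlp: MLP,
) -> float:
    """Learned log-score of one cell: per view, project keypoints, interpolate
    features, concatenate K*C into one vector and map through the MLP; the
    multi-view score is the sum of per-view scores (early-fusion contract)."""
    R = cell.pose.rotation[None]
    t = cell.pose.translation[None]
    s = _mlp_scores_vec(R, t, model, fmap_views, mlp)[0]
    if not np.isfinite(s):
        raise ValueError("non-finite activation in MLP scorer")
    return float(s)


def mlp_scorer(
    model: InstrumentModel,
    fmap_views: list[tuple[FeatureMap, CameraModel]],
    mlp: MLP,
):
    """Vectorized learned scorer over a :class:`PoseDistribution`."""

    def scorer(dist: PoseDistribution) -> np.ndarray:
        return _mlp_scores_vec(
            dist.rotations(), dist.translations(), model, fmap_views, mlp
        )

    return scorer


def infonce_loss(pos_score: float, neg_scores) -> float:
    """Contrastive loss ``-log(exp(pos) / (exp(pos) + sum exp(neg)))``.

    Computed via logsumexp, so it is stable for large score magnitudes.
    """
    neg = np.asarray(neg_scores, dtype=float).reshape(-1)
    if neg.size < 1:
        raise ValueError("need at least one negative score")
    alls = np.concatenate([[float(pos_score)], neg])
    return float(logsumexp(alls) - float(pos_score))
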