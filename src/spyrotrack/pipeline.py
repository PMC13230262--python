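"""End-to-end wiring: per-sequence pose estimation over a scene.

Ties the modules together: builds per-view scorers (analytic keypoint
reprojection or learned feature + MLP), runs the shared-grid coarse-to-fine
estimation with early or late fusion, applies the configured point
estimator, and threads recurrent feature-extractor state across frames in
sequence order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion_estimate import (
    GridBasedConfig,
    PointEstimate,
    estimate_grid_based,
    estimate_max_prob,
    estimate_weighted_avg,
    fuse_early,
    fuse_late,
)
from .geometry import CameraModel, view_axis
from .instrument import InstrumentModel
from .pose_grid import Box, GridSpec, PoseDistribution
from .recurrent_unet import RecurrentUNet, SequenceState
from .scoring import MLP, FeatureMap, ScorerConfig, analytic_scorer, mlp_scorer
from .synthetic_data import SceneData

__all__ = [
    "EstimatorConfig",
    "scaled_camera",
    "estimate_sequence",
    "estimates_to_frame",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Point-estimation strategy and its parameters."""

    method: str = "weighted_avg"  # {max_prob | weighted_avg | grid_based}
    n: int | None = None  # candidate count; defaults to 64 where used
    dx: float = 2.0
    dy: float = 2.0
    dz: float = 8.0
    cell_size: float = 1.0
    reference_camera: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("max_prob", "weighted_avg", "grid_based"):
            raise ValueError(f"unknown estimator {self.method!r}")


def scaled_camera(cam: CameraModel, width: int, height: int) -> CameraModel:
    """Camera with intrinsics rescaled to a different image resolution."""
    sx = width / cam.width
    sy = height / cam.height
    return CameraModel(
        fx=cam.fx * sx,
        fy=cam.fy * sy,
        cx=cam.cx * sx,
        cy=cam.cy * sy,
        width=width,
        height=height,
        extrinsic=cam.extrinsic,
    )


def _point_estimate(
    dist: PoseDistribution,
    model: InstrumentModel,
    est: EstimatorConfig,
    cameras: list[CameraModel],
) -> PointEstimate:
    n = 64 if est.n is None else est.n
    if est.method == "max_prob":
        if est.n is not None and est.n != 1:
            warnings.warn("estimator 'max_prob' ignores parameter n", stacklevel=2)
        return estimate_max_prob(dist, model)
    if est.method == "weighted_avg":
        return estimate_weighted_avg(dist, model, n)
    ref = cameras[min(est.reference_camera, len(cameras) - 1)]
    cfg = GridBasedConfig(
        n=n, dx=est.dx, dy=est.dy, dz=est.dz, cell_size=est.cell_size,
        depth_axis=view_axis(ref),
    )
    return estimate_grid_based(dist, model, cfg)


def estimate_sequence(
    scene: SceneData,
    grid: GridSpec,
    scorer_cfg: ScorerConfig = ScorerConfig(),
    estimator: EstimatorConfig = EstimatorConfig(),
    fusion: str = "early",  # {single | early | late}
    cameras_used: list[int] | None = None,
    unet: RecurrentUNet | None = None,
    mlp: MLP | None = None,
) -> tuple[list[PointEstimate], list[PoseDistribution]]:
    """Per-frame point estimates for one multi-camera sequence.

    With the learned backend the feature extractor's recurrent state is
    threaded across frames in sequence order (one state per camera), so
    recurrent variants integrate information from all earlier frames. A
    frame with no valid observation in any used view reuses the previous
    frame's estimate (a tracker coasts through total occlusion); if the
    first frame is unobservable the error propagates.
    """
    if fusion not in ("single", "early", "late"):
        raise ValueError(f"unknown fusion mode {fusion!r}")
    cameras_used = cameras_used if cameras_used is not None else list(
        range(len(scene.cameras))
    )
    if fusion == "single" and len(cameras_used) != 1:
        raise ValueError("fusion='single' requires exactly one camera")
    model = scene.instrument
    workspace = scene.config.workspace

    use_learned = scorer_cfg.backend == "learned"
    if use_learned:
        if unet is None or mlp is None:
            raise ValueError("learned backend requires a feature extractor and MLP")
        if scene.observation.images is None:
            raise ValueError("learned backend requires rendered images in the scene")
        # per-camera feature sequences with threaded recurrent state
        feature_seqs: dict[int, list[FeatureMap]] = {}
        size = scene.config.render_size
        for ci in cameras_used:
            state = SequenceState()
            fmaps = []
            for f in range(scene.observation.n_frames):
                img = scene.observation.images[f][ci]
                feat = unet.forward_frame(img, state)
                fmaps.append(FeatureMap(np.ascontiguousarray(feat.data.transpose(1, 2, 0))))
                state.detach()
            feature_seqs[ci] = fmaps
        cams_scaled = {
            ci: scaled_camera(scene.cameras[ci], size, size) for ci in cameras_used
        }

    def frame_views(f: int, cams: list[int]):
        if use_learned:
            return [(feature_seqs[ci][f], cams_scaled[ci]) for ci in cams]
        return [
            (scene.observation.keypoints[f][ci], scene.cameras[ci]) for ci in cams
        ]

    def view_scorer(obs_or_fmap, cam):
        if use_learned:
            return mlp_scorer(model, [(obs_or_fmap, cam)], mlp)
        return analytic_scorer(
            model, [(obs_or_fmap, cam)], scorer_cfg.analytic_sigma,
            cell_aware=scorer_cfg.analytic_cell_aware,
        )

    estimates: list[PointEstimate] = []
    dists: list[PoseDistribution] = []
    used_cams = [scene.cameras[ci] for ci in cameras_used]
    for f in range(scene.observation.n_frames):
        try:
            if fusion in ("single", "early"):
                dist = fuse_early(view_scorer, frame_views(f, cameras_used), grid, workspace)
                est = _point_estimate(dist, model, estimator, used_cams)
            else:  # late fusion: independent per-view estimation, then combine
                per_view = []
                dist = None
                for ci in cameras_used:
                    d = fuse_early(view_scorer, frame_views(f, [ci]), grid, workspace)
                    per_view.append(
                        (_point_estimate(d, model, estimator, [scene.cameras[ci]]),
                         scene.cameras[ci])
                    )
                    dist = d
                est = fuse_late(per_view)
        except ValueError as exc:
            if "unobservable" in str(exc) and estimates:
                estimates.append(estimates[-1])
                dists.append(dists[-1])
                continue
            raise
        estimates.append(est)
        dists.append(dist)
    return estimates, dists


def estimates_to_frame(estimates: list[PointEstimate], method: str) -> pd.DataFrame:
    """Estimates CSV layout: frame, tip, direction, prob, method."""
    return pd.DataFrame(
        {
            "frame": np.arange(len(estimates)),
            "tip_x": [e.tip[0] for e in estimates],
            "tip_y": [e.tip[1] for e in estimates],
            "tip_z": [e.tip[2] for e in estimates],
            "dir_x": [e.direction[0] for e in estimates],
            "dir_y": [e.direction[1] for e in estimates],
            "dir_z": [e.direction[2] for e in estimates],
            "prob": [e.prob for e in estimates],
            "method": method,
        }
    )
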