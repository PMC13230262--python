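"""Synthetic multi-camera sequences with ground truth.

Emulates the study conditions used throughout the package's experiments:
12-frame sequences at 10 FPS, one to eight randomly placed cameras looking
at the workspace center, smooth rigid instrument trajectories, checkerboard
occlusion applied to half of the second-half frames with a random offset,
a distractor occluding a single view from the sixth frame onward, and
per-frame, per-view surface-visibility ground truth.

Occlusion is modeled in observation space — keypoints and surface points
falling inside an occluder's image region are masked — rather than by
photorealistic rendering. This preserves the statistical structure the
estimator sees (per-view, per-frame information loss) at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation, Slerp

from .geometry import CameraModel, RigidPose, normalize_direction, save_camera_rig, load_camera_rig
from .instrument import InstrumentModel, default_instrument, save_instrument, load_instrument
from .pose_grid import Box
from .scoring import KeypointObservation

__all__ = [
    "SceneConfig",
    "OcclusionConfig",
    "GroundTruth",
    "SequenceObservation",
    "SceneData",
    "CheckerboardOccluder",
    "DiskOccluder",
    "generate_trajectory",
    "place_cameras",
    "render_observations",
    "generate_scene",
    "visibility",
    "save_bundle",
    "load_bundle",
    "load_scene",
    "configs_from_dicts",
]


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene."""

    n_cameras: int = 2
    n_frames: int = 12
    fps: float = 10.0
    workspace: Box = field(default_factory=lambda: Box(lo=(-100.0,) * 3, hi=(100.0,) * 3))
    camera_radius: float = 800.0
    trajectory_smoothness: int = 4  # spline control-point count
    obs_noise: float = 0.0  # px
    seed: int = 0
    image_width: int = 640
    image_height: int = 512
    focal_px: float = 600.0
    render_images: bool = False
    render_size: int = 32  # toy image side length (square), multiple of 16
    # Optional fixed orientation (w, x, y, z quaternion): the trajectory then
    # translates only. Used for reduced-DoF studies of the learned backend.
    fixed_rotation: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_cameras <= 8:
            raise ValueError("n_cameras must be in 1..8")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.trajectory_smoothness < 1:
            raise ValueError("trajectory_smoothness must be >= 1")


@dataclass(frozen=True)
class OcclusionConfig:
    """Occlusion protocol applied to the rendered observations.

    ``checkerboard`` occludes 50% of the second-half frames of each
    sequence (objects stay visible at the beginning), adding the pattern
    with a random per-view offset; only its dark squares occlude, so a
    fully covering pattern masks about half the image area. ``distractor``
    occludes one camera's view with an image-space disk from the onset
    frame (1-based, default 6) onward.
    """

    mode: str = "none"  # {none | checkerboard | distractor}
    checkerboard_square: int = 64  # px
    checkerboard_fraction: float = 0.5  # of second-half frames
    distractor_camera: int = 0
    distractor_onset: int = 6  # 1-based frame index
    distractor_radius: float = 120.0  # px

    def __post_init__(self) -> None:
        if self.mode not in ("none", "checkerboard", "distractor"):
            raise ValueError(f"unknown occlusion mode {self.mode!r}")


class CheckerboardOccluder:
    """Dark squares of a checkerboard pattern with a pixel offset."""

    def __init__(self, square: int, offset: tuple[float, float]):
        self.square = int(square)
        self.offset = (float(offset[0]), float(offset[1]))

    def contains(self, uv: np.ndarray) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        iu = np.floor((uv[..., 0] - self.offset[0]) / self.square).astype(int)
        iv = np.floor((uv[..., 1] - self.offset[1]) / self.square).astype(int)
        return (iu + iv) % 2 == 0


class DiskOccluder:
    """Image-space disk (a distractor object between camera and instrument)."""

    def __init__(self, center: tuple[float, float], radius: float):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def contains(self, uv: np.ndarray) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        d2 = np.sum((uv - self.center) ** 2, axis=-1)
        return d2 <= self.radius**2


@dataclass
class GroundTruth:
    """True poses plus per-frame, per-view visibility ground truth."""

    poses: list[RigidPose]
    visibility: np.ndarray  # (F, C) fractions in [0, 1]
    keypoint_valid: np.ndarray  # (F, C, K) bool
    occluded_frames: np.ndarray  # (F,) bool: any artificial occluder active


@dataclass
class SequenceObservation:
    """Time-ordered per-camera observations (keypoints, optional images)."""

    keypoints: list[list[KeypointObservation]]  # [frame][camera]
    images: list[list[np.ndarray]] | None = None  # [frame][camera] (H, W) in [0,1]

    @property
    def n_frames(self) -> int:
        return len(self.keypoints)

    @property
    def n_cameras(self) -> int:
        return len(self.keypoints[0])


@dataclass
class SceneData:
    config: SceneConfig
    occlusion: OcclusionConfig
    instrument: InstrumentModel
    cameras: list[CameraModel]
    observation: SequenceObservation
    ground_truth: GroundTruth


# --- generation -----------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_trajectory(cfg: SceneConfig) -> list[RigidPose]:
    """Smooth rigid trajectory sampled at ``fps`` over ``n_frames``.

    Translation is a natural cubic spline through control points drawn
    uniformly from the inner 60% of the workspace; rotation is spherical
    interpolation through random control orientations. A single control
    point yields a static sequence. Fully deterministic per seed.
    """
    rng = _rng(cfg.seed, 0)
    s = cfg.trajectory_smoothness
    inner = 0.6
    c = cfg.workspace.center
    half = 0.5 * cfg.workspace.size * inner
    ctrl_t = rng.uniform(c - half, c + half, size=(s, 3))
    ctrl_R = Rotation.random(s, random_state=np.random.RandomState(int(rng.integers(2**31))))
    if cfg.fixed_rotation is not None:
        fixed = RigidPose.from_quat(np.asarray(cfg.fixed_rotation), np.zeros(3)).rotation
    times = np.arange(cfg.n_frames) / cfg.fps
    if s == 1:
        R0 = fixed if cfg.fixed_rotation is not None else ctrl_R.as_matrix()[0]
        pose = RigidPose(R0, ctrl_t[0])
        return [pose] * cfg.n_frames
    ctrl_times = np.linspace(times[0], times[-1], s)
    spline = CubicSpline(ctrl_times, ctrl_t, bc_type="natural")
    slerp = Slerp(ctrl_times, ctrl_R)
    trans = spline(times)
    if cfg.fixed_rotation is not None:
        rots = np.broadcast_to(fixed, (cfg.n_frames, 3, 3))
    else:
        rots = slerp(times).as_matrix()
    return [RigidPose(rots[i], trans[i]) for i in range(cfg.n_frames)]


def place_cameras(cfg: SceneConfig) -> list[CameraModel]:
    """Randomly placed cameras on a sphere, all looking at the workspace center."""
    rng = _rng(cfg.seed, 1)
    center = cfg.workspace.center
    cams = []
    for _ in range(cfg.n_cameras):
        d = normalize_direction(rng.normal(size=3))
        pos = center + cfg.camera_radius * d
        z = normalize_direction(center - pos)
        up = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(up, z)) > 0.99:
            up = np.array([0.0, 1.0, 0.0])
        x = normalize_direction(np.cross(up, z))
        y = np.cross(z, x)
        R = np.stack([x, y, z])  # world -> camera rows
        extr = RigidPose(R, -R @ pos)
        cams.append(
            CameraModel(
                fx=cfg.focal_px,
                fy=cfg.focal_px,
                cx=(cfg.image_width - 1) / 2.0,
                cy=(cfg.image_height - 1) / 2.0,
                width=cfg.image_width,
                height=cfg.image_height,
                extrinsic=extr,
            )
        )
    return cams


def visibility(
    model: InstrumentModel,
    pose: RigidPose,
    camera: CameraModel,
    occluders: list,
) -> float:
    """Fraction of surface points visible under the given occluders.

    The denominator counts surface points projecting in front of the camera
    and inside the image with the occluders removed; 0/0 is defined as 0.
    """
    world = pose.transform(model.surface_points)
    pc = camera.world_to_camera(world)
    z = pc[:, 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.fx * pc[:, 0] / z + camera.cx
        v = camera.fy * pc[:, 1] / z + camera.cy
    uv = np.stack([u, v], axis=1)
    base = in_front & camera.contains(np.where(in_front[:, None], uv, 0.0))
    if base.sum() == 0:
        return 0.0
    occluded = np.zeros(len(base), dtype=bool)
    for occ in occluders:
        occluded |= np.asarray(occ.contains(uv), dtype=bool)
    return float((base & ~occluded).sum() / base.sum())


def _frame_occluders(
    occ: OcclusionConfig,
    cfg: SceneConfig,
    frame: int,
    cam_index: int,
    occluded_frames: np.ndarray,
    offsets: np.ndarray,
    distractor_center: np.ndarray | None,
) -> list:
    occluders = []
    if occ.mode == "checkerboard" and occluded_frames[frame]:
        off = offsets[frame, cam_index]
        occluders.append(CheckerboardOccluder(occ.checkerboard_square, (off[0], off[1])))
    elif occ.mode == "distractor" and cam_index == occ.distractor_camera:
        if frame + 1 >= occ.distractor_onset and distractor_center is not None:
            occluders.append(DiskOccluder(distractor_center, occ.distractor_radius))
    return occluders


def _select_occluded_frames(occ: OcclusionConfig, cfg: SceneConfig, rng) -> np.ndarray:
    flags = np.zeros(cfg.n_frames, dtype=bool)
    if occ.mode == "checkerboard":
        second_half = np.arange(cfg.n_frames // 2, cfg.n_frames)
        k = int(np.ceil(occ.checkerboard_fraction * len(second_half)))
        chosen = rng.choice(second_half, size=k, replace=False)
        flags[chosen] = True
    elif occ.mode == "distractor":
        flags[occ.distractor_onset - 1 :] = True
    return flags


def render_observations(
    trajectory: list[RigidPose],
    cameras: list[CameraModel],
    model: InstrumentModel,
    occ: OcclusionConfig,
    cfg: SceneConfig,
) -> tuple[SequenceObservation, GroundTruth]:
    """Project keypoints with noise, apply the occlusion protocol and compute
    visibility ground truth; optionally rasterize toy grayscale images."""
    rng_occ = _rng(cfg.seed, 2)
    rng_noise = _rng(cfg.seed, 3)
    F, C, K = cfg.n_frames, len(cameras), model.n_keypoints
    occluded_frames = _select_occluded_frames(occ, cfg, rng_occ)
    offsets = rng_occ.uniform(0, 2 * occ.checkerboard_square, size=(F, C, 2))

    kp_obs: list[list[KeypointObservation]] = []
    images: list[list[np.ndarray]] | None = [] if cfg.render_images else None
    vis = np.zeros((F, C))
    kp_valid = np.zeros((F, C, K), dtype=bool)

    for f in range(F):
        pose = trajectory[f]
        frame_obs = []
        frame_imgs = []
        for ci, cam in enumerate(cameras):
            world_kp = pose.transform(model.keypoints)
            pc = cam.world_to_camera(world_kp)
            z = pc[:, 2]
            in_front = z > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                u = cam.fx * pc[:, 0] / z + cam.cx
                v = cam.fy * pc[:, 1] / z + cam.cy
            uv = np.stack([u, v], axis=1)
            inside = in_front & cam.contains(np.where(in_front[:, None], uv, 0.0))

            if occ.mode == "distractor" and ci == occ.distractor_camera:
                world_sp = pose.transform(model.surface_points)
                uv_sp, front_sp = _project_surface(cam, world_sp)
                center = (
                    uv_sp[front_sp].mean(axis=0) if front_sp.any() else np.zeros(2)
                )
            else:
                center = None
            occluders = _frame_occluders(
                occ, cfg, f, ci, occluded_frames, offsets, center
            )
            occluded_kp = np.zeros(K, dtype=bool)
            for o in occluders:
                occluded_kp |= np.asarray(o.contains(uv), dtype=bool) & inside
            valid = inside & ~occluded_kp
            noisy = uv.copy()
            if cfg.obs_noise > 0:
                noisy = noisy + rng_noise.normal(0, cfg.obs_noise, size=uv.shape)
            noisy[~valid] = np.nan
            frame_obs.append(
                KeypointObservation(uv=np.nan_to_num(noisy), valid=valid,
                                    noise_scale=cfg.obs_noise)
            )
            kp_valid[f, ci] = valid
            vis[f, ci] = visibility(model, pose, cam, occluders)
            if cfg.render_images:
                frame_imgs.append(
                    _rasterize(model, pose, cam, occluders, cfg.render_size)
                )
        kp_obs.append(frame_obs)
        if cfg.render_images:
            images.append(frame_imgs)

    obs = SequenceObservation(keypoints=kp_obs, images=images)
    gt = GroundTruth(
        poses=list(trajectory),
        visibility=vis,
        keypoint_valid=kp_valid,
        occluded_frames=occluded_frames,
    )
    return obs, gt


def _project_surface(cam: CameraModel, world: np.ndarray):
    pc = cam.world_to_camera(world)
    z = pc[:, 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cam.fx * pc[:, 0] / z + cam.cx
        v = cam.fy * pc[:, 1] / z + cam.cy
    return np.stack([u, v], axis=1), in_front


def _rasterize(
    model: InstrumentModel,
    pose: RigidPose,
    cam: CameraModel,
    occluders: list,
    size: int,
) -> np.ndarray:
    """Toy grayscale render: visible surface points splat bright pixels,
    occluder regions mid-gray. Intrinsics are scaled to the render size."""
    sx = size / cam.width
    sy = size / cam.height
    img = np.zeros((size, size))
    uv_full, in_front = _project_surface(cam, pose.transform(model.surface_points))
    occluded = np.zeros(len(in_front), dtype=bool)
    for o in occluders:
        occluded |= np.asarray(o.contains(uv_full), dtype=bool)
    # occluder overlay first, instrument splat on top of what remains visible
    if occluders:
        yy, xx = np.mgrid[0:size, 0:size]
        uv_grid = np.stack([(xx + 0.5) / sx, (yy + 0.5) / sy], axis=-1)
        mask = np.zeros((size, size), dtype=bool)
        for o in occluders:
            mask |= np.asarray(o.contains(uv_grid), dtype=bool)
        img[mask] = 0.5
    u = np.round(uv_full[:, 0] * sx).astype(int)
    v = np.round(uv_full[:, 1] * sy).astype(int)
    ok = in_front & ~occluded & (u >= 0) & (u < size) & (v >= 0) & (v < size)
    img[v[ok], u[ok]] = 1.0
    return img


def generate_scene(
    cfg: SceneConfig,
    occ: OcclusionConfig | None = None,
    model: InstrumentModel | None = None,
) -> SceneData:
    """Full scene bundle: trajectory, cameras, observations, ground truth."""
    occ = occ or OcclusionConfig()
    model = model or default_instrument()
    traj = generate_trajectory(cfg)
    cams = place_cameras(cfg)
    obs, gt = render_observations(traj, cams, model, occ, cfg)
    return SceneData(
        config=cfg, occlusion=occ, instrument=model, cameras=cams,
        observation=obs, ground_truth=gt,
    )


# --- on-disk bundle -------------------------------------------------------

def _config_dicts(scene: SceneData) -> dict:
    c, o = scene.config, scene.occlusion
    return {
        "scene": {
            "n_cameras": c.n_cameras, "n_frames": c.n_frames, "fps": c.fps,
            "workspace_lo": list(map(float, c.workspace.lo)),
            "workspace_hi": list(map(float, c.workspace.hi)),
            "camera_radius": c.camera_radius,
            "trajectory_smoothness": c.trajectory_smoothness,
            "obs_noise": c.obs_noise, "seed": c.seed,
            "image_width": c.image_width, "image_height": c.image_height,
            "focal_px": c.focal_px, "render_images": c.render_images,
            "render_size": c.render_size,
            "fixed_rotation": None if c.fixed_rotation is None else list(c.fixed_rotation),
        },
        "occlusion": {
            "mode": o.mode, "checkerboard_square": o.checkerboard_square,
            "checkerboard_fraction": o.checkerboard_fraction,
            "distractor_camera": o.distractor_camera,
            "distractor_onset": o.distractor_onset,
            "distractor_radius": o.distractor_radius,
        },
    }


def configs_from_dicts(d: dict) -> tuple[SceneConfig, OcclusionConfig]:
    s = dict(d.get("scene", {}))
    lo = s.pop("workspace_lo", (-100.0,) * 3)
    hi = s.pop("workspace_hi", (100.0,) * 3)
    fr = s.pop("fixed_rotation", None)
    cfg = SceneConfig(
        workspace=Box(lo=lo, hi=hi),
        fixed_rotation=None if fr is None else tuple(fr),
        **s,
    )
    occ = OcclusionConfig(**d.get("occlusion", {}))
    return cfg, occ


def save_bundle(path: str | Path, scene: SceneData) -> None:
    """Write a scene bundle: config.json, cameras.json, instrument.json,
    gt_trajectory.csv, observations.csv, visibility.csv and (optionally)
    frames/cam{i}/{t}.png."""
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "config.json").write_text(json.dumps(_config_dicts(scene), indent=2))
    save_camera_rig(path / "cameras.json", scene.cameras)
    save_instrument(path / "instrument.json", scene.instrument)

    rows = []
    for f, pose in enumerate(scene.ground_truth.poses):
        q = pose.as_quat()
        t = pose.translation
        rows.append([f, *q, *t])
    pd.DataFrame(
        rows, columns=["frame", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]
    ).to_csv(path / "gt_trajectory.csv", index=False, float_format="%.10g")

    obs_rows = []
    for f, frame_obs in enumerate(scene.observation.keypoints):
        for c, ob in enumerate(frame_obs):
            for k in range(ob.uv.shape[0]):
                obs_rows.append(
                    [f, c, k, ob.uv[k, 0], ob.uv[k, 1], int(ob.valid[k])]
                )
    pd.DataFrame(
        obs_rows, columns=["frame", "camera", "keypoint", "u", "v", "valid"]
    ).to_csv(path / "observations.csv", index=False, float_format="%.10g")

    vis = scene.ground_truth.visibility
    vis_rows = [
        [f, c, vis[f, c], int(scene.ground_truth.occluded_frames[f])]
        for f in range(vis.shape[0])
        for c in range(vis.shape[1])
    ]
    pd.DataFrame(
        vis_rows, columns=["frame", "camera", "visibility", "occluded_frame"]
    ).to_csv(path / "visibility.csv", index=False, float_format="%.10g")

    if scene.observation.images is not None:
        import imageio.v3 as iio

        for f, frame_imgs in enumerate(scene.observation.images):
            for c, img in enumerate(frame_imgs):
                d = path / "frames" / f"cam{c}"
                d.mkdir(parents=True, exist_ok=True)
                iio.imwrite(d / f"{f:04d}.png", (img * 255).astype(np.uint8))


def load_bundle(path: str | Path):
    """Load cameras, instrument, ground-truth poses and observations.

    Returns ``(cameras, instrument, poses, keypoints, visibility_df)`` where
    ``keypoints[frame][camera]`` is a :class:`KeypointObservation`.
    """
    path = Path(path)
    cameras = load_camera_rig(path / "cameras.json")
    model = load_instrument(path / "instrument.json")
    gt = pd.read_csv(path / "gt_trajectory.csv")
    poses = [
        RigidPose.from_quat(
            row[["qw", "qx", "qy", "qz"]].to_numpy(),
            row[["tx", "ty", "tz"]].to_numpy(),
        )
        for _, row in gt.iterrows()
    ]
    obs = pd.read_csv(path / "observations.csv")
    F = int(obs["frame"].max()) + 1
    C = int(obs["camera"].max()) + 1
    K = int(obs["keypoint"].max()) + 1
    keypoints: list[list[KeypointObservation]] = []
    for f in range(F):
        row_f = obs[obs["frame"] == f]
        frame_obs = []
        for c in range(C):
            row_c = row_f[row_f["camera"] == c].sort_values("keypoint")
            frame_obs.append(
                KeypointObservation(
                    uv=row_c[["u", "v"]].to_numpy(),
                    valid=row_c["valid"].to_numpy().astype(bool),
                )
            )
        keypoints.append(frame_obs)
    vis = pd.read_csv(path / "visibility.csv")
    return cameras, model, poses, keypoints, vis


def load_scene(path: str | Path) -> SceneData:
    """Reconstruct a full :class:`SceneData` from an on-disk bundle."""
    import json

    path = Path(path)
    cfg, occ = configs_from_dicts(json.loads((path / "config.json").read_text()))
    cameras, model, poses, keypoints, vis_df = load_bundle(path)
    F = len(poses)
    C = len(cameras)
    visibility_arr = np.zeros((F, C))
    occluded = np.zeros(F, dtype=bool)
    for _, row in vis_df.iterrows():
        f, c = int(row["frame"]), int(row["camera"])
        visibility_arr[f, c] = row["visibility"]
        occluded[f] = bool(row["occluded_frame"])
    K = model.n_keypoints
    kp_valid = np.array(
        [[keypoints[f][c].valid for c in range(C)] for f in range(F)]
    ).reshape(F, C, K)
    images = None
    if (path / "frames").exists():
        import imageio.v3 as iio

        images = [
            [
                np.asarray(iio.imread(path / "frames" / f"cam{c}" / f"{f:04d}.png"),
                           dtype=float) / 255.0
                for c in range(C)
            ]
            for f in range(F)
        ]
    obs = SequenceObservation(keypoints=keypoints, images=images)
    gt = GroundTruth(
        poses=poses, visibility=visibility_arr, keypoint_valid=kp_valid,
        occluded_frames=occluded,
    )
    return SceneData(
        config=cfg, occlusion=occ, instrument=model, cameras=cameras,
        observation=obs, ground_truth=gt,
    )
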