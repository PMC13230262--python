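"""InfoNCE training of the learned scorer (feature extractor + MLP).

For every frame the cell of the finest grid level containing the true pose
is the positive hypothesis; negatives are uniform random cells at the same
level excluding the positive's cell. The contrastive loss pushes the MLP
score of the positive above the negatives.

Two sampling regimes mirror the training-regime comparison the evaluation
harness supports: per-frame shuffled batches (valid only for the
non-recurrent variant) and whole-sequence batches with backpropagation
through time (required for recurrent variants, where hidden state links
frames).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .instrument import InstrumentModel
from .pose_grid import Box, GridSpec, cell_containing, _rotations_from_index, _translations_from_index
from .recurrent_unet import RecurrentUNet, RecurrentUNetConfig, SequenceState
from .scoring import MLP
from .pipeline import scaled_camera
from .synthetic_data import SceneData

__all__ = ["TrainConfig", "train_scorer", "save_model", "load_model"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    lr: float = 1e-3
    negatives: int = 32
    level: int = 1  # grid level used for positives/negatives
    sampler: str = "sequence"  # {sequence | frame}
    camera: int = 0  # training uses a single view per scene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampler not in ("sequence", "frame"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def _candidate_poses(spec, level, workspace, rot_idx, pos_idx):
    R = _rotations_from_index(spec, level, np.asarray(rot_idx, dtype=np.int64))
    t = _translations_from_index(
        spec, level, np.asarray(pos_idx, dtype=np.int64).reshape(-1, 3), workspace
    )
    return R, t


def _frame_loss(
    net: RecurrentUNet,
    mlp_params: list[nn.Tensor],
    mlp: MLP,
    model: InstrumentModel,
    img: np.ndarray,
    cam,
    true_pose,
    spec: GridSpec,
    workspace: Box,
    cfg: TrainConfig,
    rng: np.random.Generator,
    state: SequenceState,
) -> nn.Tensor:
    feat = net.forward_frame(img, state)  # (C, H, W) Tensor
    K = model.n_keypoints

    pos_rot, pos_pos = cell_containing(spec, cfg.level, workspace, true_pose)
    na = int(np.prod(spec.rotation_shape(cfg.level)))
    shape = np.asarray(spec.position_shape(cfg.level))
    rot_idx = [pos_rot]
    pos_idx = [pos_pos]
    while len(rot_idx) < cfg.negatives + 1:
        r = int(rng.integers(na))
        p = tuple(int(x) for x in rng.integers(0, shape))
        if (r, p) != (pos_rot, pos_pos):
            rot_idx.append(r)
            pos_idx.append(p)
    R, t = _candidate_poses(spec, cfg.level, workspace, rot_idx, pos_idx)

    world = np.einsum("nij,kj->nki", R, model.keypoints) + t[:, None, :]
    pc = world @ cam.extrinsic.rotation.T + cam.extrinsic.translation
    z = pc[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cam.fx * pc[..., 0] / z + cam.cx
        v = cam.fy * pc[..., 1] / z + cam.cy
    uv = np.stack([u, v], axis=-1)
    uv[z <= 0] = -1e6  # behind camera: samples outside -> zero features

    scores = []
    for j in range(len(rot_idx)):
        f_kp = nn.bilinear_sample(feat, uv[j])  # (K, C)
        x = f_kp.reshape(1, K * feat.data.shape[0])
        s = mlp.forward_t(x, mlp_params).reshape(())
        scores.append(s)
    svec = nn.stack_scalars(scores)
    return nn.logsumexp_t(svec) - scores[0]


def train_scorer(
    scenes: list[SceneData],
    unet_config: RecurrentUNetConfig,
    spec: GridSpec,
    cfg: TrainConfig = TrainConfig(),
    mlp_hidden: tuple[int, ...] = (64, 64),
) -> tuple[RecurrentUNet, MLP, list[float]]:
    """Train the tiny feature extractor + MLP; returns per-epoch mean losses.

    Raises if a recurrent variant is combined with the per-frame shuffled
    sampler: recurrent training requires sequence batches.
    """
    if unet_config.variant != "NR" and cfg.sampler == "frame":
        raise ValueError("recurrent training requires sequence batches")
    if not scenes:
        raise ValueError("need at least one training scene")
    if scenes[0].observation.images is None:
        raise ValueError("training scenes must include rendered images")

    rng = np.random.default_rng(cfg.seed)
    net = RecurrentUNet(unet_config, rng=np.random.default_rng(cfg.seed + 1))
    model = scenes[0].instrument
    K = model.n_keypoints
    mlp = MLP(K * unet_config.feature_dim, mlp_hidden, rng=np.random.default_rng(cfg.seed + 2))
    mlp_params = mlp.tensor_params()
    params = net.parameters() + mlp_params
    opt = nn.Adam(params, lr=cfg.lr)

    size = scenes[0].config.render_size
    workspace = scenes[0].config.workspace
    cams = {
        id(s): scaled_camera(s.cameras[cfg.camera], size, size) for s in scenes
    }

    losses: list[float] = []
    for _epoch in range(cfg.epochs):
        epoch_losses = []
        if cfg.sampler == "frame":
            items = [
                (s, f) for s in scenes for f in range(s.observation.n_frames)
            ]
            order = rng.permutation(len(items))
            for i in order:
                s, f = items[i]
                state = SequenceState()  # fresh state: frame-independent
                opt.zero_grad()
                loss = _frame_loss(
                    net, mlp_params, mlp, model,
                    s.observation.images[f][cfg.camera], cams[id(s)],
                    s.ground_truth.poses[f], spec, workspace, cfg, rng, state,
                )
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
        else:  # whole-sequence batches with BPTT
            for s in scenes:
                state = SequenceState()
                opt.zero_grad()
                total = None
                F = s.observation.n_frames
                for f in range(F):
                    loss = _frame_loss(
                        net, mlp_params, mlp, model,
                        s.observation.images[f][cfg.camera], cams[id(s)],
                        s.ground_truth.poses[f], spec, workspace, cfg, rng, state,
                    )
                    total = loss if total is None else total + loss
                mean_loss = (1.0 / F) * total
                mean_loss.backward()
                opt.step()
                epoch_losses.append(float(mean_loss.data))
        losses.append(float(np.mean(epoch_losses)))
    return net, mlp, losses


def save_model(path: str | Path, net: RecurrentUNet, mlp: MLP) -> None:
    """Single archive with all weights + a JSON manifest of shapes/configs."""
    named = {**net.named_params(), **mlp.named_params()}
    cfg = net.config
    named["__config__"] = np.frombuffer(
        json.dumps(
            {
                "variant": cfg.variant,
                "channels": list(cfg.channels),
                "in_channels": cfg.in_channels,
                "feature_dim": cfg.feature_dim,
                "kernel_size": cfg.kernel_size,
                "gru_mode": cfg.gru_mode,
                "mlp_hidden": [w.shape[1] for w in mlp.weights[:-1]],
                "mlp_in": mlp.in_dim,
            }
        ).encode(),
        dtype=np.uint8,
    )
    nn.save_params(path, named)


def load_model(path: str | Path) -> tuple[RecurrentUNet, MLP]:
    named = nn.load_params(path)
    meta = json.loads(bytes(named.pop("__config__")).decode())
    config = RecurrentUNetConfig(
        variant=meta["variant"],
        channels=tuple(meta["channels"]),
        in_channels=meta["in_channels"],
        feature_dim=meta["feature_dim"],
        kernel_size=meta["kernel_size"],
        gru_mode=meta["gru_mode"],
    )
    net = RecurrentUNet(config)
    net.load_named(named)
    mlp = MLP(meta["mlp_in"], tuple(meta["mlp_hidden"]))
    mlp.load_named(named)
    return net, mlp
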