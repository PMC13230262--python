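"""Train the learned (image-based) pose scorer on rendered scenes.

Instead of hand-provided 2D keypoints, the learned backend extracts a dense
feature map from each rendered image with a (recurrent) U-Net, samples it
bilinearly at the projected keypoint locations of every candidate pose, and
scores the concatenated features with a small MLP.  Training minimizes an
InfoNCE loss: the ground-truth cell competes against negative pose cells.

This demo is deliberately tiny (one rotation cell, a 4x4x4 -> 8x8x8 position
grid, 64 px renders, ~1 minute) but exercises the full path: rendering,
feature extraction, training, and two-view early fusion at inference.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from spyrotrack.pose_grid import Box, GridSpec, cell_containing, estimate_distribution
from spyrotrack.pose_grid import _rotations_from_index
from spyrotrack.pipeline import scaled_camera
from spyrotrack.recurrent_unet import RecurrentUNetConfig, extract_features
from spyrotrack.scoring import mlp_scorer
from spyrotrack.synthetic_data import SceneConfig, generate_scene
from spyrotrack.training import TrainConfig, train_scorer

spec = GridSpec(rotation_base_shape=(1, 1, 1), position_base_shape=(4, 4, 4),
                max_level=1, top_k=None)
workspace = Box(lo=(-60.0,) * 3, hi=(60.0,) * 3)

# Freeze orientation at the single rotation cell's center so the toy network
# only has to localize position.
R0 = _rotations_from_index(spec, 0, np.array([0]))[0]
q = Rotation.from_matrix(R0).as_quat()
fixed_q = (q[3], q[0], q[1], q[2])  # wxyz


def make_scene(seed):
    return generate_scene(SceneConfig(
        n_cameras=2, n_frames=2, seed=seed, workspace=workspace,
        camera_radius=400.0, render_images=True, render_size=64,
        fixed_rotation=fixed_q, obs_noise=0.0,
    ))


train_scenes = [make_scene(s) for s in range(5)]
net_cfg = RecurrentUNetConfig(variant="NR", channels=(3, 4, 5, 6, 7), feature_dim=8)
train_cfg = TrainConfig(epochs=20, negatives=32, level=1, sampler="frame",
                        camera=0, seed=0)

net, mlp, losses = train_scorer(train_scenes, net_cfg, spec, train_cfg,
                                mlp_hidden=(32,))
print(f"InfoNCE loss: {losses[0]:.3f} (epoch 1) -> {losses[-1]:.3f} (epoch {len(losses)})")

print("\nheld-out scenes, two-view early fusion on the learned scores:")
for seed in range(5, 10):
    scene = make_scene(seed)
    views = []
    for c in range(2):
        cam = scaled_camera(scene.cameras[c], 64, 64)
        fmap = extract_features(net, [scene.observation.images[0][c]])[0]
        views.append((fmap, cam))
    dist = estimate_distribution(mlp_scorer(scene.instrument, views, mlp),
                                 spec, workspace)
    am = dist.argmax()
    _, gt_pos = cell_containing(spec, 1, workspace, scene.ground_truth.poses[0])
    d = int(np.abs(dist.pos_index[am] - np.array(gt_pos)).max())
    print(f"  seed {seed}: argmax cell {dist.pos_index[am].tolist()}, "
          f"ground truth {list(gt_pos)}, Chebyshev distance {d}")
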