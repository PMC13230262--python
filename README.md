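# spyrotrack

Recurrent multi-view 6DoF pose-distribution estimation for marker-less
tracking of a rigid surgical-style instrument.

Instead of regressing a single pose, `spyrotrack` estimates a **probability
distribution over SE(3)** on a hierarchical grid: the pose space (Euler-box
rotations × translation octree) is scored coarsely, the most probable cells
are subdivided 64-way and rescored, and the procedure repeats to the desired
resolution. Observations from any number of calibrated cameras are fused by
summing per-view log-scores on the shared world-frame grid (early fusion),
which is what makes the depth ambiguity of a single view collapse as soon as
a second view is added. Scoring is either **analytic** (Gaussian reprojection
likelihood of observed 2D keypoints — no training needed) or **learned**
(a small, optionally recurrent U-Net produces per-pixel features that are
sampled at projected keypoints and scored by an MLP trained with InfoNCE).
Recurrent U-Net variants (ConvGRU cells at configurable encoder/decoder
levels) let features integrate information over a video sequence while
remaining strictly causal.

The package includes a deterministic synthetic-scene generator (camera rigs
on a sphere, spline trajectories, a checkerboard occlusion protocol, optional
shaft renders), point estimators that reduce the distribution to a tip/
direction estimate, an evaluation suite (tip error, angle error, RMSD/RMSAD
smoothness, visibility-binned breakdowns), and a four-stage CLI
(`simulate → estimate → evaluate`, plus `train` for the learned backend).
See [docs/methods.md](docs/methods.md) for the model and its numerical
choices.

## Worked example

Two cameras observe a noise-free instrument; the pose distribution is
refined over three levels and reduced to point estimates
(`examples/02_hierarchical_estimation.py`):

```python
from spyrotrack.fusion_estimate import estimate_max_prob, fuse_early
from spyrotrack.pose_grid import Box, GridSpec
from spyrotrack.scoring import analytic_scorer
from spyrotrack.synthetic_data import SceneConfig, generate_scene

workspace = Box(lo=(-100.0,) * 3, hi=(100.0,) * 3)
scene = generate_scene(SceneConfig(n_cameras=2, n_frames=2, seed=3))
spec = GridSpec()  # 72 x 64 base cells, 3 refinements, top-512 beam

def view_scorer(obs, cam):
    return analytic_scorer(scene.instrument, [(obs, cam)])

views = [(scene.observation.keypoints[0][c], scene.cameras[c]) for c in range(2)]
dist = fuse_early(view_scorer, views, spec, workspace)
est = estimate_max_prob(dist, scene.instrument)
```

Output:

```
base grid:        4608 cells
finest cell size: 10.83 mm (diagonal), 10.10 deg (angular radius)

final distribution has 32768 cells at level 3
top-5 cells by probability:
  prob=0.9634  rot_index=19265 pos_index=[16, 13, 23]
  prob=0.0265  rot_index=20466 pos_index=[16, 13, 23]
  prob=0.0096  rot_index=19217 pos_index=[17, 13, 24]
  prob=0.0002  rot_index=16767 pos_index=[16, 13, 22]
  prob=0.0001  rot_index=20418 pos_index=[17, 13, 24]
max_prob      tip error =   4.86 mm  (prob mass used: 0.963)
weighted_avg  tip error =   4.82 mm  (prob mass used: 1.000)
```

The error sits at the level-3 quantization floor (half the 10.8 mm cell
diagonal); deeper grids localize proportionally better.

### What extra cameras buy

With 2 px keypoint noise (`examples/03_multiview_fusion.py`, 8 scenes):

```
median tip error over 8 scenes, 2 px keypoint noise:
cams  total (mm)  depth-axis (mm)
   1       42.74            42.59
   2        4.30             0.57
   4        3.26             0.80
```

A single view leaves the depth axis nearly unconstrained; early fusion of a
second view removes it. At finer grid resolution (level 8, tempered scorer)
the medians on 30 scenes continue monotonically: 74.1 / 3.16 / 1.48 / 1.12 mm
for 1/2/4/8 cameras, matching a continuous maximum-likelihood reference.

### Learned backend

`examples/05_train_learned_scorer.py` trains the tiny U-Net + MLP scorer on
five rendered toy scenes (~1 min CPU):

```
InfoNCE loss: 3.329 (epoch 1) -> 0.536 (epoch 20)

held-out scenes, two-view early fusion on the learned scores:
  seed 5: argmax cell [3, 5, 1], ground truth [3, 5, 1], Chebyshev distance 0
  seed 6: argmax cell [4, 4, 3], ground truth [5, 2, 5], Chebyshev distance 2
  seed 7: argmax cell [4, 1, 3], ground truth [5, 1, 4], Chebyshev distance 1
  seed 8: argmax cell [4, 3, 2], ground truth [4, 3, 3], Chebyshev distance 1
  seed 9: argmax cell [3, 3, 4], ground truth [2, 3, 5], Chebyshev distance 1
```

## CLI

```sh
spyrotrack simulate --config run.yaml --out bundle/          # synthetic scene bundle
spyrotrack estimate --config run.yaml --bundle bundle/ --out est/
spyrotrack evaluate --bundle bundle/ --estimates est/ --out eval/
spyrotrack train    --config run.yaml --bundles bundle/ --out model.npz
spyrotrack estimate ... --weights model.npz                  # learned backend
```

Every stage writes a `run_manifest.json` with seeds and timings. A minimal
config:

```yaml
scene:
  n_cameras: 2
  n_frames: 3
  seed: 7
grid:
  rotation_base_shape: [4, 3, 6]
  position_base_shape: [4, 4, 4]
  max_level: 3
  top_k: 512
estimator:
  method: max_prob   # or weighted_avg | grid_based
```

## Reproduction

- `examples/` — five narrative scripts covering simulation, hierarchical
  estimation, multi-view fusion, occlusion/evaluation, and training.
- `scripts/acceptance.py --seed 1 --out results/acceptance.json` — computes
  the headline quantities (oracle deviations, parameter recovery, the
  camera-count sweep, occlusion statistics, learned-backend training) on
  seeded data.
- `tests/test_acceptance.py` — one property-based test per acceptance
  criterion; the rest of `tests/` covers each module against closed-form
  oracles and independent reimplementations.
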