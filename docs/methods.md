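# Methods

This note records the model implemented by `spyrotrack`, its parameters and
units, the scope of the synthetic-data generator, and the numerical choices
that affect results.

## Problem setting

A rigid instrument (a surgical-tool-like shaft with `K` 3D keypoints, default
`K = 8`, shaft length 120 mm) moves through a bounded workspace observed by
`C` calibrated pinhole cameras. Per frame, each camera yields noisy 2D
keypoint observations (or a rendered image, for the learned backend). The
task is to recover the 6DoF pose per frame and, from it, the tip position and
shaft direction.

Units: distances in millimetres, image quantities in pixels, angles in
degrees at the API surface (radians internally where noted).

## Pose distribution on a hierarchical SE(3) grid

The pose space is discretized as the product of

- a **rotation grid**: an axis-aligned box partition of ZYX Euler angles
  (yaw ∈ [0, 2π), pitch ∈ [−π/2, π/2], roll ∈ [0, 2π)), base shape
  `(4, 3, 6)` = 72 cells; and
- a **translation octree** over the workspace box, base shape `(4, 4, 4)`.

Each cell is represented by its **center point**: the pose whose Euler
angles and translation are the cell midpoints. Estimation is coarse-to-fine:

1. score every base cell (4608 by default);
2. normalize scores to probabilities with a softmax,
   `p_i = exp(s_i − logsumexp(s))`;
3. keep the `top_k` cells (default 512), subdivide each 64-way
   (8 rotation × 8 position children by halving every axis), rescore,
   renormalize;
4. repeat until `max_level` (default 3).

Cells are stored in canonical ascending cell-id order
(`rot_index * n_pos + flat_pos_index`, x-major); argmax and sorting use
stable order so probability ties break toward the lower cell id, making
results reproducible bit-for-bit.

The Euler-box grid is deliberately simple: it is not a uniform partition of
SO(3) (cells near the pitch poles cover less solid angle), but it is exact
to enumerate, trivially subdividable, and sufficient for the property checks
and synthetic studies the package targets. `rotation_cell_angular_radius`
reports a sampled bound on the geodesic radius of a cell at a given level.

### Probability concentration across levels

The probability assigned to the single cell containing the true pose is
**not** monotone across refinement levels, and cannot be in general under
center-point scoring: a coarse containing cell can absorb nearly all mass
(its competitors' centers score poorly), while after subdivision the same
region is shared among 64 children and mass near cell boundaries splits
between neighbours. The guarantees that do hold, and are tested, are
argmax-level ones: with a scorer sharply peaked at the true pose, the final
argmax cell lies within one cell of the cell containing the truth (with
wrap-around on yaw/roll), and the 1-cell neighbourhood around the truth
carries the majority of the mass.

### Quantization floor

A level-`L` grid cannot localize better than its cell size: the position
floor is about half the cell diagonal, and the rotation floor maps to tip
error through the shaft arm (60 mm × sin of the angular half-cell). At the
default `max_level = 3` in a ±100 mm workspace this floor is ≈ 3–6 mm.
Studies of effects smaller than the floor must use a deeper grid; e.g. the
camera-count sweep at 2 px noise (where 4 → 8 cameras is worth ≈ 0.2 mm)
uses `max_level = 8` (floor ≈ 0.25 mm), sized a priori by comparing against
a continuous maximum-likelihood fit of the same objective.

## Scoring

### Analytic (keypoint) scorer

Given observed keypoints `u_k` and a candidate pose, each valid keypoint
contributes `−‖π(R x_k + t) − u_k‖² / (2σ²)` with `σ = 2 px` by default;
keypoints projecting behind the camera contribute a fixed penalty of −50
each (finite, so normalization never produces −inf). A pose for which *no*
keypoint is valid in *any* view raises an "unobservable pose" error rather
than returning a silent constant. This is the log-likelihood of an isotropic
Gaussian pixel-noise model, so with matched noise the argmax is the
maximum-likelihood pose up to grid quantization.

**Cell-aware tempering** (opt-in, `cell_aware=True`): evaluating a sharp
likelihood at coarse cell centers ranks cells almost arbitrarily once the
posterior is much narrower than a cell — all centers reproject tens of
pixels away — and hierarchical pruning then retains a biased beam. The
effect grows with the number of fused views (each view summed doubles the
sharpness). The tempered scorer inflates the noise scale per level and per
hypothesis: with world-space cell radius
`ρ_L = position half-diagonal + arm · sin(rotation half-cell bound)` and
hypothesis depth `z` in a view with focal length `f`,

```
σ_eff² = σ² + (f · ρ_L / z)²
```

with the matching `−½ log(σ_eff²/σ²)` normalization per valid keypoint.
This approximates integrating the likelihood over the cell instead of
evaluating its center; the correction vanishes at fine levels. The rotation
half-cell uses an O(1) bound (half the sum of the Euler cell widths, by the
rotation triangle inequality) rather than the exact sampled radius, which
would be intractable at deep levels.

### Learned scorer

A small U-Net maps each image to a dense feature map (`feature_dim`
channels). For a candidate pose, keypoints are projected into the view, the
feature map is sampled bilinearly at those locations (out-of-image points
yield zero features), and the `K × feature_dim` concatenation is scored by
an MLP. Multi-view scores are summed (early fusion).

The U-Net is a 5-level residual encoder–decoder; input height and width
must be multiples of 16. Recurrence is added by ConvGRU cells at
configurable encoder/decoder levels, giving four variants:

| variant | recurrent placements | behaviour |
|---|---|---|
| NR | none | memoryless |
| RB | encoder level 5 (bottleneck) | coarse memory |
| RC | encoder {2, 5}, decoder {3, 5} | mixed |
| RA | all levels 1–5, both paths | full memory |

Parameter counts order NR < RB < RC < RA. The ConvGRU supports two candidate
formulations: `standard` (`h̃ = tanh(W_x x + W_h (r ⊙ h) + b)`) and
`verbatim` (reset gate omitted from the candidate). Two exact identities pin
the implementation: a saturated update gate reproduces `h_{t−1}`
bit-for-bit, and all-zero weights give `h_t = 0.5 · h_{t−1}` exactly.
Recurrence is causal by construction; state lives in a `SequenceState` that
can be `reset()` (bit-identical restarts) or detached between sequences.

Training minimizes InfoNCE: `loss = −s⁺ + logsumexp([s⁺, s₁⁻, …, s_N⁻])`
with the true-pose cell positive and sampled negative cells. Recurrent
variants require whole-sequence batches (per-frame shuffling is rejected
with an error); non-recurrent variants may shuffle frames. The autodiff core
is a small reverse-mode engine over NumPy (im2col convolution, pooling,
bilinear sampling, logsumexp) with Adam; gradients are checked against
finite differences in the test suite.

## Multi-view fusion

- **Early fusion** (default): per-view log-scores are computed on the shared
  world-frame grid and summed before normalization — the probabilistically
  correct combination for independent views, and the variant that actually
  triangulates (single-view depth ambiguity collapses once a second view is
  added).
- **Late fusion**: each view is estimated independently; tip and rear points
  are averaged with weights proportional to per-view estimate probabilities
  (uniform fallback if all are zero). Cheap, but it averages rather than
  triangulates; rotation averaging is deliberately out of scope.

## Point estimators

- `max_prob`: center pose of the argmax cell.
- `weighted_avg`: probability-weighted average of tip and rear points over
  the top-`n` cells (default `n = 64`; `n = 1` reduces to `max_prob`). The
  reported `prob` is the pre-renormalization mass of the cells used. When
  cells are much smaller than the posterior width this interpolates sub-cell
  and approximates the posterior mean.
- `grid_based`: accumulates candidate probabilities into a cuboid around
  each accumulation-grid node — half-extents `dx = dy = 2 mm` in-plane and
  `dz = 8 mm` along the depth axis of a reference camera (default camera 0),
  spacing `cell_size = 1 mm` — and returns the node with the highest
  accumulated mass. Ties break to the node nearest the probability-weighted
  mean tip, then lexicographically in (x, y, z). The rear point comes from
  the highest-probability candidate whose cuboid covers the chosen node.

## Synthetic-data generator

Scope: geometrically consistent multi-camera scenes for property checks and
trend studies — not a photorealistic renderer.

- Cameras on a sphere (default radius 800 mm, focal length 600 px, 640×512
  image) looking at the workspace center (default box ±100 mm).
- Trajectories: cubic splines in position, Slerp in orientation, through
  random control points; `smoothness = 1` gives a static pose;
  `fixed_rotation` freezes orientation.
- Observations add isotropic Gaussian pixel noise (`obs_noise`, px).
- Occlusion protocol (`checkerboard`): for a 12-frame sequence, exactly
  ⌈0.5 · 6⌉ = 3 of frames 7–12 (1-based) are occluded, never the first
  half. A distractor disk can additionally occlude one camera from a chosen
  onset frame.
- The visibility metric is the ratio of visible keypoints to keypoints that
  would be visible without occluders (0/0 → 0).
- Optional ray-traced shaft renders (`render_images`) feed the learned
  backend.
- Determinism: all randomness derives from `numpy.random.SeedSequence`
  streams spawned from the scene seed; scenes are reproducible bit-for-bit.

## Evaluation metrics

- **Tip error** (mm): Euclidean distance between estimated and true tip.
- **Angle error** (deg): angle between estimated and true shaft directions.
- **RMSD / RMSAD** (mm per frame / deg per frame): root-mean-square
  frame-to-frame tip displacement / direction change — smoothness measures,
  requiring ≥ 2 frames.
- Visibility-binned summaries partition [0, 1] into fixed-width bins (last
  bin closed), reporting counts and per-bin means (NaN for empty bins).
- All metrics are invariant under a common world-frame rigid transform of
  prediction and ground truth; summaries report mean, sample SD (flagged
  undefined for a single record), median and IQR.

## Limitations

- The Euler-box rotation grid is non-uniform on SO(3); pole cells are
  over-resolved.
- Center-point scoring approximates cell-integrated mass; see the
  concentration note. The tempered scorer mitigates but does not eliminate
  this at coarse levels.
- The learned backend is a CPU-scale demonstration (tiny U-Net, toy scenes);
  it validates the training loop and inference path, not application-grade
  accuracy.
- Late fusion averages endpoints and can land between modes when views
  disagree strongly.
- The generator's occlusion model removes keypoints; it does not model
  keypoint displacement from specularity or blur.
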