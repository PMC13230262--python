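import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spyrotrack.geometry import CameraModel, RigidPose
from spyrotrack.pose_grid import Box, GridSpec, base_grid, cell_containing, normalize
from spyrotrack.scoring import (
    BEHIND_CAMERA_PENALTY,
    MLP,
    FeatureMap,
    KeypointObservation,
    analytic_score,
    analytic_scorer,
    infonce_loss,
    interpolate_features,
    mlp_score,
)
from spyrotrack.synthetic_data import SceneConfig, generate_scene


def front_camera():
    return CameraModel(
        fx=600.0, fy=600.0, cx=320.0, cy=256.0, width=640, height=512,
        extrinsic=RigidPose(np.eye(3), np.array([0.0, 0.0, 800.0])),
    )


def exact_observation(model, pose, cam):
    from spyrotrack.scoring import _project_keypoints

    uv, in_front = _project_keypoints(
        pose.rotation[None], pose.translation[None], model, cam
    )
    return KeypointObservation(uv=uv[0], valid=in_front[0])


class TestAnalyticScore:
    def test_exact_observation_scores_zero(self, instrument):
        cam = front_camera()
        pose = RigidPose.identity()
        obs = exact_observation(instrument, pose, cam)
        from spyrotrack.pose_grid import GridCell

        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=pose)
        assert analytic_score(cell, instrument, [(obs, cam)]) == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_keypoint_scores_minus_half(self, instrument):
        cam = front_camera()
        pose = RigidPose.identity()
        obs = exact_observation(instrument, pose, cam)
        uv = obs.uv.copy()
        uv[0, 0] += 2.0  # displace one keypoint by sigma=2 px
        obs2 = KeypointObservation(uv=uv, valid=obs.valid)
        from spyrotrack.pose_grid import GridCell

        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=pose)
        assert analytic_score(cell, instrument, [(obs2, cam)], sigma=2.0) == pytest.approx(
            -0.5, abs=1e-12
        )

    def test_behind_camera_penalty_per_valid_keypoint(self, instrument):
        cam = front_camera()
        pose = RigidPose(np.eye(3), np.array([0.0, 0.0, -2000.0]))  # behind
        obs = exact_observation(instrument, RigidPose.identity(), cam)
        from spyrotrack.pose_grid import GridCell

        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=pose)
        s = analytic_score(cell, instrument, [(obs, cam)])
        assert s == pytest.approx(BEHIND_CAMERA_PENALTY * int(obs.valid.sum()))

    def test_view_order_invariance(self, instrument, rng):
        cams = [front_camera(),
                CameraModel(fx=500.0, fy=500.0, cx=320.0, cy=256.0, width=640,
                            height=512,
                            extrinsic=RigidPose.from_quat([0.9, 0.3, 0.1, 0.0],
                                                          [10.0, 0.0, 700.0]))]
        pose = RigidPose.from_quat(rng.normal(size=4), rng.uniform(-50, 50, 3))
        views = [(exact_observation(instrument, pose, c), c) for c in cams]
        noisy = [
            (KeypointObservation(v.uv + rng.normal(0, 1, v.uv.shape), v.valid), c)
            for v, c in views
        ]
        from spyrotrack.pose_grid import GridCell

        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=pose)
        assert analytic_score(cell, instrument, noisy) == pytest.approx(
            analytic_score(cell, instrument, noisy[::-1]), abs=1e-10
        )

    def test_all_invalid_view_is_neutral(self, instrument):
        cam = front_camera()
        pose = RigidPose.identity()
        obs = exact_observation(instrument, pose, cam)
        dead = KeypointObservation(uv=obs.uv, valid=np.zeros_like(obs.valid))
        from spyrotrack.pose_grid import GridCell

        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=pose)
        s1 = analytic_score(cell, instrument, [(obs, cam)])
        s2 = analytic_score(cell, instrument, [(obs, cam), (dead, cam)])
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_all_views_invalid_raises_unobservable(self, instrument):
        cam = front_camera()
        obs = exact_observation(instrument, RigidPose.identity(), cam)
        dead = KeypointObservation(uv=obs.uv, valid=np.zeros_like(obs.valid))
        with pytest.raises(ValueError, match="unobservable pose"):
            analytic_score(
                base_grid(GridSpec(), Box(lo=(-1,) * 3, hi=(1,) * 3)).cell(0),
                instrument,
                [(dead, cam)],
            )

    def test_noise_free_argmax_is_true_cell(self, workspace):
        """On an exhaustive small grid the true pose's cell wins with
        noise-free observations from the scene generator."""
        spec = GridSpec(
            rotation_base_shape=(4, 3, 6), position_base_shape=(4, 4, 4),
            max_level=0,
        )
        scene = generate_scene(SceneConfig(n_cameras=2, n_frames=2, seed=5))
        model = scene.instrument
        f = 0
        views = [
            (scene.observation.keypoints[f][c], scene.cameras[c])
            for c in range(2)
        ]
        scorer = analytic_scorer(model, views)
        dist = normalize(base_grid(spec, workspace))
        dist.log_score = scorer(dist)
        dist = normalize(dist)
        am = dist.argmax()
        ri, pi = cell_containing(spec, 0, workspace, scene.ground_truth.poses[f])
        # at this coarse resolution the winner may be a direct neighbor of
        # the containing cell (cells are compared by their center score)
        assert np.abs(dist.pos_index[am] - np.array(pi)).max() <= 1
        na, nb, nc = spec.rotation_base_shape
        got = int(dist.rot_index[am])
        gi, gj, gk = got // (nb * nc), (got // nc) % nb, got % nc
        ti, tj, tk = ri // (nb * nc), (ri // nc) % nb, ri % nc
        assert min(abs(gi - ti), na - abs(gi - ti)) <= 1  # yaw wraps
        assert abs(gj - tj) <= 1
        assert min(abs(gk - tk), nc - abs(gk - tk)) <= 1  # roll wraps


class TestInterpolateFeatures:
    def test_integer_pixels_exact(self, rng):
        vals = rng.normal(size=(8, 10, 3))
        fmap = FeatureMap(vals)
        feats, inside = interpolate_features(fmap, np.array([[4.0, 2.0], [0.0, 0.0]]))
        assert inside.all()
        np.testing.assert_allclose(feats[0], vals[2, 4], atol=1e-14)
        np.testing.assert_allclose(feats[1], vals[0, 0], atol=1e-14)

    def test_midpoint_is_mean_of_neighbors(self, rng):
        vals = rng.normal(size=(4, 4, 2))
        feats, _ = interpolate_features(FeatureMap(vals), np.array([[1.5, 2.0]]))
        np.testing.assert_allclose(feats[0], (vals[2, 1] + vals[2, 2]) / 2, atol=1e-14)

    def test_constant_map_everywhere_constant(self):
        vals = np.full((6, 6, 2), 3.25)
        pts = np.array([[0.3, 4.7], [2.5, 2.5], [5.0, 0.01]])
        feats, inside = interpolate_features(FeatureMap(vals), pts)
        assert inside.all()
        np.testing.assert_allclose(feats, 3.25, atol=1e-14)

    def test_outside_yields_zero_and_flag(self):
        vals = np.ones((4, 4, 1))
        feats, inside = interpolate_features(
            FeatureMap(vals), np.array([[-0.5, 1.0], [1.0, 3.5], [np.nan, 1.0]])
        )
        assert not inside.any()
        np.testing.assert_array_equal(feats, 0.0)

    def test_non_finite_feature_map_rejected(self):
        vals = np.ones((4, 4, 1))
        vals[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            FeatureMap(vals)


class TestMLPScore:
    def _fmap_views(self, instrument, n_views, const=1.0):
        cam = front_camera()
        H, W = cam.height, cam.width
        fmap = FeatureMap(np.full((H, W, 2), const))
        return [(fmap, cam)] * n_views

    def test_zero_weights_give_bias(self, instrument):
        from spyrotrack.pose_grid import GridCell

        mlp = MLP(in_dim=2 * instrument.n_keypoints, hidden=(4,))
        for W in mlp.weights:
            W[:] = 0.0
        mlp.biases[-1][:] = 1.5
        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=RigidPose.identity())
        s = mlp_score(cell, instrument, self._fmap_views(instrument, 1), mlp)
        assert s == pytest.approx(1.5, abs=1e-12)

    def test_duplicated_view_doubles_score(self, instrument, rng):
        from spyrotrack.pose_grid import GridCell

        mlp = MLP(in_dim=2 * instrument.n_keypoints, hidden=(8,), rng=rng)
        cell = GridCell(level=0, rot_index=0, pos_index=(0, 0, 0), pose=RigidPose.identity())
        one = mlp_score(cell, instrument, self._fmap_views(instrument, 1, 0.7), mlp)
        two = mlp_score(cell, instrument, self._fmap_views(instrument, 2, 0.7), mlp)
        assert two == pytest.approx(2 * one, abs=1e-10)


class TestInfoNCE:
    def test_uniform_scores_give_log_n(self):
        assert infonce_loss(0.0, np.zeros(255)) == pytest.approx(np.log(256), abs=1e-12)

    def test_dominant_positive_goes_to_zero(self):
        assert infonce_loss(1000.0, np.zeros(5)) == pytest.approx(0.0, abs=1e-9)

    def test_example_log4(self):
        # pos=0, three negatives each contributing weight 1 -> ln 4
        assert infonce_loss(0.0, [0.0, 0.0, 0.0]) == pytest.approx(np.log(4), abs=1e-12)

    def test_needs_negatives(self):
        with pytest.raises(ValueError):
            infonce_loss(0.0, [])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_neg_log_softmax_oracle(self, seed):
        r = np.random.default_rng(seed)
        pos = float(r.normal() * 10)
        neg = r.normal(size=int(r.integers(1, 20))) * 10
        # direct softmax oracle with explicit max-subtraction
        alls = np.concatenate([[pos], neg])
        m = alls.max()
        p = np.exp(pos - m) / np.exp(alls - m).sum()
        assert infonce_loss(pos, neg) == pytest.approx(-np.log(p), abs=1e-10)

    def test_shift_invariance(self):
        a = infonce_loss(1.0, [0.0, 2.0])
        b = infonce_loss(1001.0, [1000.0, 1002.0])
        assert a == pytest.approx(b, abs=1e-9)


class TestCellAwareScorer:
    """Tempered (cell-aware) analytic scoring."""

    def _base_dist(self, workspace):
        spec = GridSpec(
            rotation_base_shape=(2, 1, 2), position_base_shape=(2, 2, 2),
            max_level=0,
        )
        return spec, base_grid(spec, workspace)

    def test_exact_center_observation_oracle(self, instrument):
        """With observations generated exactly at a cell-center pose, the
        quadratic term vanishes and the tempered score reduces to the
        normalization term -0.5 * K * log(var / sigma^2)."""
        workspace = Box(lo=(-100.0,) * 3, hi=(100.0,) * 3)
        spec, dist = self._base_dist(workspace)
        cam = front_camera()
        i = 5  # arbitrary cell
        pose = dist.cell(i).pose
        obs = exact_observation(instrument, pose, cam)
        assert np.all(obs.valid)
        scorer = analytic_scorer(instrument, [(obs, cam)], cell_aware=True)
        got = scorer(dist)[i]

        sigma = 2.0
        half_diag = 0.5 * spec.position_cell_diagonal(workspace, 0)
        widths = np.array([2 * np.pi, np.pi, 2 * np.pi])
        ang = min(0.5 * float(np.sum(widths / np.array(spec.rotation_shape(0)))),
                  np.pi / 2)
        arm = float(np.max(np.linalg.norm(instrument.keypoints, axis=1)))
        radius = half_diag + arm * np.sin(ang)
        z = (pose.translation @ cam.extrinsic.rotation.T
             + cam.extrinsic.translation)[2]
        var = sigma**2 + (600.0 * radius / z) ** 2
        K = instrument.keypoints.shape[0]
        want = -0.5 * K * np.log(var / sigma**2)
        assert got == pytest.approx(want, rel=1e-12)

    def test_correction_vanishes_at_fine_levels(self, instrument):
        """At a deep level the cell radius is tiny, so tempered and plain
        scores agree closely."""
        from spyrotrack.pose_grid import PoseDistribution

        workspace = Box(lo=(-100.0,) * 3, hi=(100.0,) * 3)
        spec = GridSpec(max_level=0)
        level = 12
        dist = PoseDistribution(
            level=level, spec=spec, workspace=workspace,
            rot_index=np.array([0, 123456, 999999], dtype=np.int64),
            pos_index=np.array([[0, 0, 0], [100, 200, 300], [5000, 1, 2]],
                               dtype=np.int64),
            log_score=np.zeros(3),
        )
        scene = generate_scene(SceneConfig(n_cameras=1, n_frames=2, seed=4))
        views = [(scene.observation.keypoints[0][0], scene.cameras[0])]
        plain = analytic_scorer(scene.instrument, views)(dist)
        tempered = analytic_scorer(scene.instrument, views, cell_aware=True)(dist)
        np.testing.assert_allclose(tempered, plain, rtol=1e-3, atol=1e-3)

    def test_differs_from_plain_at_coarse_level(self, instrument):
        workspace = Box(lo=(-100.0,) * 3, hi=(100.0,) * 3)
        _spec, dist = self._base_dist(workspace)
        scene = generate_scene(SceneConfig(n_cameras=1, n_frames=2, seed=4))
        views = [(scene.observation.keypoints[0][0], scene.cameras[0])]
        plain = analytic_scorer(scene.instrument, views)(dist)
        tempered = analytic_scorer(scene.instrument, views, cell_aware=True)(dist)
        assert not np.allclose(plain, tempered)
        # smoothing makes coarse scores much less extreme
        assert np.abs(tempered).max() < np.abs(plain).max()
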