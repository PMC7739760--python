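import numpy as np
import pytest

from mocapkit.body25 import LEFT_RIGHT_PAIRS, NAME_TO_INDEX
from mocapkit.formats_io import read_keypoint_dir
from mocapkit.reference_kinematics import harrington_hjc, midpoint_center
from mocapkit.synthetic_scene import (
    SceneConfig,
    generate_skeleton_motion,
    make_camera_ring,
    make_reference_markers,
    render_observations,
    simulate_scene,
)

SEGMENTS = [
    ("r_hip", "r_knee"),
    ("r_knee", "r_ankle"),
    ("l_hip", "l_knee"),
    ("l_knee", "l_ankle"),
    ("r_shoulder", "r_elbow"),
    ("r_elbow", "r_wrist"),
    ("l_shoulder", "l_elbow"),
    ("l_elbow", "l_wrist"),
    ("r_ankle", "r_heel"),
    ("r_ankle", "r_big_toe"),
    ("l_ankle", "l_small_toe"),
    ("mid_hip", "neck"),
    ("neck", "nose"),
]


class TestSkeletonMotion:
    @pytest.mark.parametrize("task", ["walk", "jump", "throw"])
    def test_segment_lengths_constant(self, task):
        traj = generate_skeleton_motion(SceneConfig(task=task, duration=2.0, seed=0))
        for a, b in SEGMENTS:
            d = np.linalg.norm(traj.point(a) - traj.point(b), axis=1)
            assert d.std() < 1e-6 * d.mean(), (a, b)

    def test_jump_pelvis_has_single_global_maximum_mid_trial(self):
        traj = generate_skeleton_motion(SceneConfig(task="jump", duration=2.0, seed=0))
        z = traj.point("mid_hip")[:, 2]
        peak = np.argmax(z)
        assert 0.3 * len(z) < peak < 0.9 * len(z)
        assert (z < z[peak]).sum() == len(z) - 1  # unique maximum

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(task="walk", duration=1.0, seed=42)
        a = generate_skeleton_motion(cfg)
        b = generate_skeleton_motion(cfg)
        np.testing.assert_array_equal(a.data, b.data)


class TestCameraRing:
    def test_control_points_recover_truth_cameras(self, camera_ring):
        from mocapkit.calibration import dlt_calibrate

        cams, points = camera_ring
        for cid, truth in cams.items():
            cal = dlt_calibrate(points, cid)
            np.testing.assert_allclose(cal.L, truth.L, rtol=1e-8)

    def test_two_camera_ring_triangulates(self):
        from mocapkit.calibration import project_many
        from mocapkit.reconstruction import triangulate

        cams, _ = make_camera_ring(SceneConfig(n_cameras=2))
        p = np.array([100.0, -50.0, 1200.0])
        obs = {
            cid: np.r_[project_many(c, p[None, :])[0], 1.0] for cid, c in cams.items()
        }
        res = triangulate(cams, obs)
        np.testing.assert_allclose(res.point, p, atol=1e-6)

    def test_centered_skeleton_projects_inside_all_images(self, camera_ring, walk_truth):
        from mocapkit.calibration import project_many

        cams, _ = camera_ring
        mid = walk_truth.n_frames // 2
        pts = walk_truth.data[mid]
        for cam in cams.values():
            uv = project_many(cam, pts)
            assert (uv[:, 0] > 0).all() and (uv[:, 0] < cam.image_width).all()
            assert (uv[:, 1] > 0).all() and (uv[:, 1] < cam.image_height).all()


class TestRenderObservations:
    def test_zero_corruption_zero_noise_closure(self, camera_ring, walk_config, walk_truth):
        from mocapkit.reconstruction import ReconstructionParams, reconstruct_sequence

        cams, _ = camera_ring
        cfg = SceneConfig(**{**walk_config.__dict__, "pixel_noise_sigma": 0.0})
        streams, gt = render_observations(walk_truth, cams, cfg)
        assert not gt.swap_log and not gt.outlier_log and not gt.miss_log
        traj = reconstruct_sequence(
            streams, cams, ReconstructionParams(exclude_px=None), frame_rate=cfg.frame_rate
        )
        np.testing.assert_allclose(traj.data, walk_truth.data, atol=1e-6)

    def test_swap_fraction_within_binomial_interval(self, camera_ring, walk_truth, walk_config):
        cams, _ = camera_ring
        p = 0.1
        cfg = SceneConfig(**{**walk_config.__dict__, "swap_prob": p, "seed": 9})
        _, gt = render_observations(walk_truth, cams, cfg)
        n_trials = len(cams) * walk_truth.n_frames * len(LEFT_RIGHT_PAIRS)
        assert n_trials >= 10_000
        frac = len(gt.swap_log) / n_trials
        margin = 4 * np.sqrt(p * (1 - p) / n_trials)
        assert abs(frac - p) < margin

    def test_corruption_logs_invert_bit_exactly(self, camera_ring, walk_truth, walk_config):
        cams, _ = camera_ring
        cfg = SceneConfig(
            **{
                **walk_config.__dict__,
                "swap_prob": 0.05,
                "outlier_prob": 0.02,
                "miss_prob": 0.02,
                "seed": 13,
            }
        )
        streams, gt = render_observations(walk_truth, cams, cfg)
        restored = {cid: np.stack([f.keypoints for f in frames]) for cid, frames in streams.items()}
        for cid, t, k, orig in reversed(gt.miss_log):
            restored[cid][t, k] = orig
        for cid, t, k, orig in reversed(gt.outlier_log):
            restored[cid][t, k] = orig
        for cid, t, (l, r) in reversed(gt.swap_log):
            restored[cid][t, [l, r]] = restored[cid][t, [r, l]]
        for cid in streams:
            np.testing.assert_array_equal(restored[cid], gt.clean_obs[cid])

    def test_files_on_disk_reread_identically(self, tmp_path, camera_ring, walk_truth, walk_config):
        cams, _ = camera_ring
        streams, _ = render_observations(walk_truth, cams, walk_config, out_dir=tmp_path)
        for cid in list(cams)[:2]:
            back = read_keypoint_dir(tmp_path / cid, cid)
            assert len(back) == len(streams[cid])
            for a, b in zip(streams[cid], back):
                np.testing.assert_allclose(a.keypoints, b.keypoints, atol=1e-6)


class TestReferenceMarkers:
    def test_zero_noise_midpoints_equal_truth_joints(self):
        cfg = SceneConfig(task="walk", duration=1.0, seed=2, marker_noise_sigma_mm=0.0)
        markers = make_reference_markers(cfg)
        truth = generate_skeleton_motion(cfg, frame_rate=cfg.marker_rate)
        for side in "rl":
            for joint in ("elbow", "wrist", "knee", "ankle"):
                mid = midpoint_center(
                    markers.markers[f"{side}_{joint}_lateral"],
                    markers.markers[f"{side}_{joint}_medial"],
                )
                np.testing.assert_allclose(
                    mid, truth.point(f"{side}_{joint}"), atol=1e-9
                )

    def test_harrington_centres_land_on_truth_hips(self):
        cfg = SceneConfig(task="walk", duration=1.0, seed=2, marker_noise_sigma_mm=0.0)
        markers = make_reference_markers(cfg)
        truth = generate_skeleton_motion(cfg, frame_rate=cfg.marker_rate)
        left, right = harrington_hjc(
            markers.markers["l_asis"],
            markers.markers["r_asis"],
            markers.markers["l_psis"],
            markers.markers["r_psis"],
        )
        np.testing.assert_allclose(left, truth.point("l_hip"), atol=1e-9)
        np.testing.assert_allclose(right, truth.point("r_hip"), atol=1e-9)

    def test_marker_rate_matches_config(self):
        cfg = SceneConfig(duration=1.0, seed=0)
        markers = make_reference_markers(cfg)
        assert markers.frame_rate == 200.0
        assert markers.n_frames == 201


class TestSimulateScene:
    def test_scene_artifacts_written_and_consistent(self, tmp_path):
        cfg = SceneConfig(duration=1.0, seed=4)
        scene = simulate_scene(cfg, tmp_path)
        assert (tmp_path / "sync.csv").exists()
        assert (tmp_path / "control_points.csv").exists()
        assert (tmp_path / "scene.json").exists()
        lengths = {cid: len(s) for cid, s in scene["streams"].items()}
        for cid, e in scene["sync"].event_frames.items():
            assert 0 <= e < lengths[cid]

    def test_determinism_per_seed(self):
        a = simulate_scene(SceneConfig(duration=1.0, seed=8))
        b = simulate_scene(SceneConfig(duration=1.0, seed=8))
        for cid in a["streams"]:
            np.testing.assert_array_equal(
                np.stack([f.keypoints for f in a["streams"][cid]]),
                np.stack([f.keypoints for f in b["streams"][cid]]),
            )
        assert a["sync"].event_frames == b["sync"].event_frames
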