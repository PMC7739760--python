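"""Synthetic multi-camera capture scenes.

Generates ground-truth 25-keypoint skeleton motion, a ring of virtual
projective cameras with surveyed control points, noisy per-camera 2D
keypoint observations with injected pose-estimator failure modes
(left-right label swaps, gross outlier detections, missed detections),
and a synthetic marker-based reference whose derived joint centres
coincide with the ground-truth joints by construction. Every module of
the pipeline is thereby testable end to end without recordings.

The skeleton archetypes are kinematic caricatures of the three motor
tasks (walking, countermovement jump, overarm throw), built by rotating
fixed-length segment vectors so all inter-keypoint segment lengths are
constant to machine precision. They exercise every algorithm; they are
not biomechanical models.

All randomness flows from the seed in :class:`SceneConfig`; identical
configs give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .body25 import LEFT_RIGHT_PAIRS, NAME_TO_INDEX, N_KEYPOINTS
from .calibration import CameraDLT, ControlPoint, project_many
from .exceptions import ConfigError
from .formats_io import PoseFrame2D, Trajectory3D, write_keypoint_dir
from .reference_kinematics import HARRINGTON_COEFFS, MarkerSet

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_skeleton_motion",
    "make_camera_ring",
    "render_observations",
    "make_reference_markers",
    "inject_swaps",
    "simulate_scene",
]

_CONDITIONS = {
    "1K": {"frame_rate": 120.0, "image_size": (1920, 1080)},
    "4K": {"frame_rate": 30.0, "image_size": (3840, 2160)},
}

# skeleton dimensions, mm; hip width chosen so the synthetic pelvis
# markers (PW = 240, PD = 120) place the Harrington hip centres exactly
# on the truth hip keypoints
PELVIS_WIDTH = 240.0
PELVIS_DEPTH = 120.0
HIP_HALF_WIDTH = HARRINGTON_COEFFS["ml_pw"] * PELVIS_WIDTH + HARRINGTON_COEFFS["ml_0"]  # 86.5
_AP_OFF = HARRINGTON_COEFFS["ap_pd"] * PELVIS_DEPTH + HARRINGTON_COEFFS["ap_0"]  # -38.7
_IS_OFF = HARRINGTON_COEFFS["is_pw"] * PELVIS_WIDTH + HARRINGTON_COEFFS["is_0"]  # -82.9

THIGH = 420.0
SHANK = 430.0
TORSO = 540.0
SHOULDER_HALF_WIDTH = 190.0
UPPER_ARM = 280.0
FOREARM = 250.0

_FOOT_LOCAL = {  # in a foot frame rotated about X by the foot pitch
    "big_toe": np.array([0.0, 150.0, -60.0]),
    "small_toe": np.array([35.0, 140.0, -60.0]),
    "heel": np.array([0.0, -60.0, -70.0]),
}
_HEAD_LOCAL = {  # constant offsets from the neck
    "nose": np.array([0.0, 90.0, 130.0]),
    "r_eye": np.array([32.0, 80.0, 160.0]),
    "l_eye": np.array([-32.0, 80.0, 160.0]),
    "r_ear": np.array([75.0, 0.0, 150.0]),
    "l_ear": np.array([-75.0, 0.0, 150.0]),
}


@dataclass
class SceneConfig:
    """Study-like scene parameters.

    The two capture conditions mirror the validated setup: "1K" is
    1920x1080 at 120 Hz, "4K" is 3840x2160 at 30 Hz, five cameras on a
    ring. ``pixel_noise_sigma`` (px) models the pose estimator's jitter;
    the corruption probabilities are per pair (swaps) or per keypoint
    (outliers, misses) per frame per camera and default to zero.
    Confidences are Beta(8, 2) for clean and Beta(2, 4) for corrupted
    detections. ``preroll_max`` staggers the cameras' record starts (in
    frames) so synchronization has real work to do.
    """

    task: str = "walk"
    condition: str = "1K"
    duration: float = 4.0
    n_cameras: int = 5
    ring_radius_mm: float = 4000.0
    camera_heights_mm: tuple = (1300.0, 1900.0, 2500.0)
    frame_rate: float | None = None
    image_size: tuple | None = None
    pixel_noise_sigma: float = 2.0
    swap_prob: float = 0.0
    outlier_prob: float = 0.0
    miss_prob: float = 0.0
    conf_clean: tuple = (8.0, 2.0)
    conf_corrupt: tuple = (2.0, 4.0)
    marker_rate: float = 200.0
    marker_noise_sigma_mm: float = 0.5
    preroll_max: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.condition not in _CONDITIONS:
            raise ConfigError(f"condition must be one of {sorted(_CONDITIONS)}")
        if self.task not in ("walk", "jump", "throw"):
            raise ConfigError("task must be walk|jump|throw")
        if self.n_cameras < 2:
            raise ConfigError("need at least two cameras")
        for p in (self.swap_prob, self.outlier_prob, self.miss_prob):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("corruption probabilities must be in [0, 1]")
        if self.frame_rate is None:
            self.frame_rate = _CONDITIONS[self.condition]["frame_rate"]
        if self.image_size is None:
            self.image_size = _CONDITIONS[self.condition]["image_size"]


@dataclass
class GroundTruth:
    """Everything the scene knows about itself: the truth trajectory,
    per-camera clean (noisy but uncorrupted) observations, the exact
    corruption logs, per-camera record-start offsets, and the cameras'
    true parameters."""

    truth: Trajectory3D
    cams: dict[str, CameraDLT]
    clean_obs: dict[str, np.ndarray]  # cam -> (T, 25, 3) u, v, conf
    swap_log: list = field(default_factory=list)  # (cam, frame, (l, r))
    outlier_log: list = field(default_factory=list)  # (cam, frame, kp, (u, v, c))
    miss_log: list = field(default_factory=list)  # (cam, frame, kp, (u, v, c))
    offsets: dict[str, int] = field(default_factory=dict)
    event_frame_truth: int = 0


def _rot_x(angle: np.ndarray) -> np.ndarray:
    """Rotation matrices about world X, shape (T, 3, 3)."""
    c, s = np.cos(angle), np.sin(angle)
    R = np.zeros(angle.shape + (3, 3))
    R[..., 0, 0] = 1.0
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    return R


def _sagittal_dir(theta: np.ndarray) -> np.ndarray:
    """Unit segment direction in the sagittal plane: theta = 0 points
    straight down, positive swings forward (+Y)."""
    return np.stack([np.zeros_like(theta), np.sin(theta), -np.cos(theta)], axis=-1)


def generate_skeleton_motion(
    config: SceneConfig, frame_rate: float | None = None, n_frames: int | None = None
) -> Trajectory3D:
    """Ground-truth 25-keypoint motion for the configured task.

    The motion is an analytic function of time, so it can be evaluated
    at any rate (``frame_rate`` overrides the camera rate — used to
    produce the 200 Hz marker-based reference of the same movement).
    All limb segment lengths are constant to machine precision.
    """
    rate = frame_rate if frame_rate is not None else config.frame_rate
    if n_frames is None:
        n_frames = int(round(config.duration * rate)) + 1
    t = np.arange(n_frames) / rate
    T = config.duration

    kp = np.zeros((n_frames, N_KEYPOINTS, 3))
    x_hat = np.array([1.0, 0.0, 0.0])

    if config.task == "walk":
        f = 0.9  # stride frequency, Hz
        pelvis = np.stack(
            [
                20.0 * np.sin(2 * np.pi * f * t),
                -700.0 + 1100.0 * t,
                930.0 + 15.0 * np.sin(4 * np.pi * f * t),
            ],
            axis=1,
        )
        th_r = 0.40 * np.sin(2 * np.pi * f * t)
        th_l = 0.40 * np.sin(2 * np.pi * f * t + np.pi)
        kn_r = 0.35 * 0.5 * (1 - np.cos(2 * np.pi * f * t + 0.8))
        kn_l = 0.35 * 0.5 * (1 - np.cos(2 * np.pi * f * t + np.pi + 0.8))
        foot_r = 0.15 * np.sin(2 * np.pi * f * t + 0.4)
        foot_l = 0.15 * np.sin(2 * np.pi * f * t + np.pi + 0.4)
        arm_r = 0.30 * np.sin(2 * np.pi * f * t + np.pi)
        arm_l = 0.30 * np.sin(2 * np.pi * f * t)
        elbow_flex_r = np.full_like(t, 0.35)
        elbow_flex_l = np.full_like(t, 0.35)
        arm_dir_r = arm_dir_l = None
    elif config.task == "jump":
        squat = 260.0 * np.exp(-(((t - 0.45 * T) / (0.18 * T)) ** 2))
        flight = 430.0 * np.exp(-(((t - 0.70 * T) / (0.07 * T)) ** 2))
        pelvis = np.stack(
            [np.zeros_like(t), np.zeros_like(t), 930.0 - squat + flight], axis=1
        )
        bend = squat / 260.0  # 0..1 squat depth
        th_r = th_l = 0.9 * bend
        kn_r = kn_l = 1.6 * bend
        foot_r = foot_l = 0.1 * bend
        arm_r = arm_l = -0.8 * bend  # arms swing back in the squat
        elbow_flex_r = elbow_flex_l = 0.3 + 0.2 * bend
        arm_dir_r = arm_dir_l = None
    else:  # throw
        pelvis = np.stack(
            [np.zeros_like(t), 150.0 * t / T, np.full_like(t, 930.0)], axis=1
        )
        f = 0.5
        th_r = 0.15 * np.sin(2 * np.pi * f * t)
        th_l = 0.15 * np.sin(2 * np.pi * f * t + np.pi)
        kn_r = kn_l = 0.10 * 0.5 * (1 - np.cos(2 * np.pi * f * t))
        foot_r = foot_l = np.zeros_like(t)
        # rapid unilateral arm rotation: cocking then acceleration
        s = np.clip((t - 0.40 * T) / (0.25 * T), 0.0, 1.0)
        smooth = s * s * (3 - 2 * s)
        psi = -0.6 + 3.0 * smooth
        tilt = 0.35  # arm plane tilted out of the sagittal plane
        arm_dir_r = np.stack(
            [np.sin(tilt) * np.sin(psi), np.cos(tilt) * np.sin(psi), -np.cos(psi)],
            axis=-1,
        )
        arm_r = psi  # only used for the forearm continuation below
        arm_l = np.full_like(t, 0.2)
        elbow_flex_r = 0.9 * (1 - smooth) + 0.1
        elbow_flex_l = np.full_like(t, 0.35)
        arm_dir_l = None

    mid_hip = pelvis
    r_hip = pelvis + HIP_HALF_WIDTH * x_hat
    l_hip = pelvis - HIP_HALF_WIDTH * x_hat

    def leg(hip, th, kn, foot_pitch):
        knee = hip + THIGH * _sagittal_dir(th)
        ankle = knee + SHANK * _sagittal_dir(th - kn)
        R = _rot_x(foot_pitch)
        parts = {
            name: ankle + np.einsum("tij,j->ti", R, local)
            for name, local in _FOOT_LOCAL.items()
        }
        return knee, ankle, parts

    r_knee, r_ankle, r_foot = leg(r_hip, th_r, kn_r, foot_r)
    l_knee, l_ankle, l_foot = leg(l_hip, th_l, kn_l, foot_l)

    neck = pelvis + np.array([0.0, 0.0, TORSO])
    r_shoulder = neck + SHOULDER_HALF_WIDTH * x_hat + np.array([0.0, 0.0, -30.0])
    l_shoulder = neck - SHOULDER_HALF_WIDTH * x_hat + np.array([0.0, 0.0, -30.0])

    def arm(shoulder, psi, elbow_flex, explicit_dir):
        d1 = explicit_dir if explicit_dir is not None else _sagittal_dir(psi)
        elbow = shoulder + UPPER_ARM * d1
        d2 = _sagittal_dir(psi + elbow_flex) if explicit_dir is None else None
        if d2 is None:
            # rotate the explicit direction by the elbow flexion about X
            R = _rot_x(elbow_flex)
            d2 = np.einsum("tij,tj->ti", R, explicit_dir)
        wrist = elbow + FOREARM * d2
        return elbow, wrist

    r_elbow, r_wrist = arm(r_shoulder, arm_r, elbow_flex_r, arm_dir_r)
    l_elbow, l_wrist = arm(l_shoulder, arm_l, elbow_flex_l, arm_dir_l)

    head = {name: neck + off for name, off in _HEAD_LOCAL.items()}

    parts = {
        "nose": head["nose"],
        "neck": neck,
        "r_shoulder": r_shoulder,
        "r_elbow": r_elbow,
        "r_wrist": r_wrist,
        "l_shoulder": l_shoulder,
        "l_elbow": l_elbow,
        "l_wrist": l_wrist,
        "mid_hip": mid_hip,
        "r_hip": r_hip,
        "r_knee": r_knee,
        "r_ankle": r_ankle,
        "l_hip": l_hip,
        "l_knee": l_knee,
        "l_ankle": l_ankle,
        "r_eye": head["r_eye"],
        "l_eye": head["l_eye"],
        "r_ear": head["r_ear"],
        "l_ear": head["l_ear"],
        "l_big_toe": l_foot["big_toe"],
        "l_small_toe": l_foot["small_toe"],
        "l_heel": l_foot["heel"],
        "r_big_toe": r_foot["big_toe"],
        "r_small_toe": r_foot["small_toe"],
        "r_heel": r_foot["heel"],
    }
    for name, series in parts.items():
        kp[:, NAME_TO_INDEX[name], :] = series
    valid = np.ones((n_frames, N_KEYPOINTS), dtype=bool)
    return Trajectory3D(kp, valid, rate)


def make_camera_ring(config: SceneConfig) -> tuple[dict[str, CameraDLT], list[ControlPoint]]:
    """Virtual cameras on a ring around the capture volume, plus 12
    non-coplanar control points (four calibration-pole placements, three
    heights each) observed exactly by every camera.

    Camera truth coefficients come from an exact projective construction
    (pinhole intrinsics times a look-at extrinsic), rescaled to the
    11-parameter DLT normalization.
    """
    width, height = config.image_size
    target = np.array([0.0, 0.0, 1000.0])
    up = np.array([0.0, 0.0, 1.0])
    f = 0.9 * width
    cams: dict[str, CameraDLT] = {}
    for i in range(config.n_cameras):
        ang = 2 * np.pi * i / config.n_cameras + 0.3
        h = config.camera_heights_mm[i % len(config.camera_heights_mm)]
        C = np.array(
            [config.ring_radius_mm * np.cos(ang), config.ring_radius_mm * np.sin(ang), h]
        )
        z_cam = target - C
        z_cam = z_cam / np.linalg.norm(z_cam)
        x_cam = np.cross(z_cam, up)
        x_cam = x_cam / np.linalg.norm(x_cam)
        y_cam = np.cross(z_cam, x_cam)
        R = np.stack([x_cam, y_cam, z_cam])
        tvec = -R @ C
        K = np.array([[f, 0.0, width / 2.0], [0.0, f, height / 2.0], [0.0, 0.0, 1.0]])
        P = K @ np.hstack([R, tvec[:, None]])
        P = P / P[2, 3]
        L = np.concatenate([P[0], P[1], P[2, :3]])
        cams[f"cam{i}"] = CameraDLT(f"cam{i}", L, width, height)

    points: list[ControlPoint] = []
    pole_xy = [(-600.0, -600.0), (600.0, -600.0), (600.0, 600.0), (-600.0, 600.0)]
    heights = (200.0, 950.0, 1700.0)
    k = 0
    for px, py in pole_xy:
        for hz in heights:
            world = np.array([px, py, hz])
            obs = {}
            for cid, cam in cams.items():
                uv = project_many(cam, world[None, :])[0]
                obs[cid] = (float(uv[0]), float(uv[1]))
            points.append(ControlPoint(f"cp{k}", world, obs))
            k += 1
    return cams, points


def render_observations(
    truth: Trajectory3D,
    cams: dict[str, CameraDLT],
    config: SceneConfig,
    out_dir=None,
) -> tuple[dict[str, list[PoseFrame2D]], GroundTruth]:
    """Project the truth into every camera and corrupt like a per-frame
    pose estimator: Gaussian pixel noise, per-camera left-right label
    swaps, gross outlier relocations, missed detections, and Beta-model
    confidences (lower for corrupted points).

    All events are logged exactly; applying the logged inverses to the
    corrupted observations recovers the clean (noisy, uncorrupted)
    observations bit-exactly. With ``out_dir`` the per-camera keypoint
    files are also written in the estimator's JSON layout.
    """
    rng = np.random.default_rng(config.seed)
    n = truth.n_frames
    gt = GroundTruth(truth, cams, {})
    streams: dict[str, list[PoseFrame2D]] = {}
    flat_truth = truth.data.reshape(-1, 3)
    for cid in sorted(cams):
        cam = cams[cid]
        proj = project_many(cam, flat_truth).reshape(n, N_KEYPOINTS, 2)
        obs = np.empty((n, N_KEYPOINTS, 3))
        obs[:, :, :2] = proj + rng.normal(0.0, config.pixel_noise_sigma, proj.shape)
        obs[:, :, 2] = rng.beta(*config.conf_clean, size=(n, N_KEYPOINTS))
        gt.clean_obs[cid] = obs.copy()

        if config.swap_prob > 0:
            hit = rng.random((n, len(LEFT_RIGHT_PAIRS))) < config.swap_prob
            for j, (left, right) in enumerate(LEFT_RIGHT_PAIRS):
                for tt in np.flatnonzero(hit[:, j]):
                    obs[tt, [left, right]] = obs[tt, [right, left]]
                    gt.swap_log.append((cid, int(tt), (left, right)))
        if config.outlier_prob > 0:
            hit = rng.random((n, N_KEYPOINTS)) < config.outlier_prob
            for tt, kk in zip(*np.nonzero(hit)):
                gt.outlier_log.append((cid, int(tt), int(kk), tuple(obs[tt, kk])))
                obs[tt, kk, 0] = rng.uniform(0, cam.image_width)
                obs[tt, kk, 1] = rng.uniform(0, cam.image_height)
                obs[tt, kk, 2] = rng.beta(*config.conf_corrupt)
        if config.miss_prob > 0:
            hit = rng.random((n, N_KEYPOINTS)) < config.miss_prob
            for tt, kk in zip(*np.nonzero(hit)):
                gt.miss_log.append((cid, int(tt), int(kk), tuple(obs[tt, kk])))
                obs[tt, kk] = 0.0

        streams[cid] = [PoseFrame2D(cid, t, obs[t]) for t in range(n)]
        if out_dir is not None:
            write_keypoint_dir(Path(out_dir) / cid, streams[cid], prefix=cid)
    return streams, gt


def inject_swaps(
    traj: Trajectory3D, swap_prob: float, rng: np.random.Generator, pairs=LEFT_RIGHT_PAIRS
) -> tuple[Trajectory3D, list[tuple[int, tuple[int, int]]]]:
    """Exchange homologous labels directly in a 3D trajectory with the
    given per-pair per-frame probability; returns the corrupted copy and
    the (frame, pair) log. Models the post-triangulation appearance of
    consistent multi-camera label swaps."""
    out = traj.copy()
    log = []
    hit = rng.random((traj.n_frames, len(pairs))) < swap_prob
    for j, (left, right) in enumerate(pairs):
        for t in np.flatnonzero(hit[:, j]):
            out.data[t, [left, right]] = out.data[t, [right, left]]
            out.valid[t, [left, right]] = out.valid[t, [right, left]]
            log.append((int(t), (left, right)))
    log.sort()
    return out, log


def make_reference_markers(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> MarkerSet:
    """Synthetic marker-based reference at the marker system's rate
    (200 Hz by default), spanning the same motion as the camera-rate
    truth.

    Lateral/medial (and anterior/posterior shoulder) marker pairs are
    placed symmetrically about the truth joints, so their midpoints
    equal the truth exactly before marker noise; ASIS/PSIS markers are
    placed so the Harrington regression lands exactly on the truth hip
    keypoints (pelvis width 240 mm, depth 120 mm). White marker noise of
    ``marker_noise_sigma_mm`` is then added.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    truth = generate_skeleton_motion(config, frame_rate=config.marker_rate)
    idx = NAME_TO_INDEX
    x_hat = np.array([1.0, 0.0, 0.0])
    y_hat = np.array([0.0, 1.0, 0.0])
    markers: dict[str, np.ndarray] = {}

    for side, sign in (("r", 1.0), ("l", -1.0)):
        sh = truth.data[:, idx[f"{side}_shoulder"], :]
        markers[f"{side}_shoulder_anterior"] = sh + 50.0 * y_hat
        markers[f"{side}_shoulder_posterior"] = sh - 50.0 * y_hat
        for j, off in (("elbow", 35.0), ("wrist", 30.0), ("knee", 45.0), ("ankle", 40.0)):
            joint = truth.data[:, idx[f"{side}_{j}"], :]
            markers[f"{side}_{j}_lateral"] = joint + sign * off * x_hat
            markers[f"{side}_{j}_medial"] = joint - sign * off * x_hat

    pelvis = truth.data[:, idx["mid_hip"], :]
    mid_asis = pelvis + np.array([0.0, -_AP_OFF, -_IS_OFF])  # (0, +38.7, +82.9)
    markers["r_asis"] = mid_asis + (PELVIS_WIDTH / 2) * x_hat
    markers["l_asis"] = mid_asis - (PELVIS_WIDTH / 2) * x_hat
    mid_psis = mid_asis - PELVIS_DEPTH * y_hat
    markers["r_psis"] = mid_psis + 40.0 * x_hat
    markers["l_psis"] = mid_psis - 40.0 * x_hat

    if config.marker_noise_sigma_mm > 0:
        for name in sorted(markers):
            markers[name] = markers[name] + rng.normal(
                0.0, config.marker_noise_sigma_mm, markers[name].shape
            )
    return MarkerSet(markers, config.marker_rate)


def simulate_scene(config: SceneConfig, out_dir=None) -> dict:
    """Generate a complete trial: truth motion, camera ring and control
    points, per-camera keypoint streams with staggered record starts and
    a sync table, and the 200 Hz reference markers.

    Returns a dict with keys truth, cams, control_points, streams,
    ground_truth, sync, markers, event_time. With ``out_dir`` all
    artifacts are written to disk in the pipeline's file formats.
    """
    from .calibration import write_calibration, write_control_points
    from .formats_io import write_trajectory
    from .synchronization import SyncInfo, write_sync_file

    rng = np.random.default_rng(config.seed + 7)
    rate = config.frame_rate
    pre = config.preroll_max
    n_trial = int(round(config.duration * rate)) + 1
    n_total = n_trial + pre
    truth = generate_skeleton_motion(config, n_frames=n_total)
    cams, control_points = make_camera_ring(config)
    full_streams, gt = render_observations(truth, cams, config, out_dir=None)

    event_frame_truth = pre  # light switch-on at trial start
    gt.event_frame_truth = event_frame_truth
    offsets = {cid: int(rng.integers(0, pre + 1)) for cid in sorted(cams)}
    gt.offsets = offsets
    streams: dict[str, list[PoseFrame2D]] = {}
    event_frames: dict[str, int] = {}
    for cid, frames in full_streams.items():
        a = offsets[cid]
        sliced = frames[a:]
        streams[cid] = [
            PoseFrame2D(cid, j, fr.keypoints) for j, fr in enumerate(sliced)
        ]
        event_frames[cid] = event_frame_truth - a
    sync = SyncInfo(event_frames, rate, "start")
    markers = make_reference_markers(config)
    event_time = event_frame_truth / rate

    scene = {
        "truth": truth,
        "cams": cams,
        "control_points": control_points,
        "streams": streams,
        "ground_truth": gt,
        "sync": sync,
        "markers": markers,
        "event_time": event_time,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cid, frames in streams.items():
            write_keypoint_dir(out / "keypoints" / cid, frames, prefix=cid)
        write_control_points(out / "control_points.csv", control_points, sorted(cams))
        write_calibration(out / "cameras_truth.csv", [cams[c] for c in sorted(cams)])
        write_sync_file(out / "sync.csv", sync)
        write_trajectory(truth, out / "ground_truth.trc")
        write_trajectory(markers.to_trajectory(), out / "reference_markers.trc")
        import json

        meta = asdict(config)
        meta["event_time_s"] = event_time
        meta["event_frame_truth"] = event_frame_truth
        meta["offsets"] = offsets
        (out / "scene.json").write_text(json.dumps(meta, indent=2, default=list))
    return scene
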