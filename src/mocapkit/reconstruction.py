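"""Multi-camera triangulation of 2D keypoints into world coordinates.

Each keypoint in each frame is estimated by linear (algebraic) least
squares on the stacked DLT back-projection equations — two equations per
camera, rearranged so the unknowns are (X, Y, Z):

    (u L9 - L1) X + (u L10 - L2) Y + (u L11 - L3) Z = L4 - u
    (v L9 - L5) X + (v L10 - L6) Y + (v L11 - L7) Z = L8 - v

Observations are gated by detection confidence, optionally weighted by
it, and a camera whose reprojection residual is anomalously large in a
frame can be excluded iteratively before the final solve. Frames with
fewer than two usable cameras are marked invalid rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .body25 import KEYPOINT_NAMES, N_KEYPOINTS
from .calibration import CameraDLT, project_many
from .exceptions import LengthError
from .formats_io import PoseFrame2D, Trajectory3D

__all__ = [
    "TriangulationResult",
    "ReconstructionParams",
    "triangulate",
    "exclude_outlier_cameras",
    "reconstruct_sequence",
]


@dataclass
class TriangulationResult:
    """One triangulated point: position, the cameras that contributed,
    and the RMS reprojection error over those cameras."""

    point: np.ndarray | None  # (3,) mm, None when invalid
    n_cameras_used: int
    rms_reprojection: float
    used_cameras: frozenset

    @property
    def valid(self) -> bool:
        return self.point is not None


@dataclass
class ReconstructionParams:
    """Tunables for sequence reconstruction.

    ``conf_min``: detections below this confidence are ignored (default
    0.1 — excludes the estimator's near-zero junk without discarding
    plausible ones). ``exclude_px``: reprojection-residual threshold in
    pixels for iterative bad-camera exclusion; None disables; "auto"
    scales the 20 px full-HD default by image width.
    """

    conf_min: float = 0.1
    weight_by_confidence: bool = True
    exclude_px: float | str | None = "auto"

    def resolved_exclude_px(self, image_width: int) -> float | None:
        if self.exclude_px is None:
            return None
        if self.exclude_px == "auto":
            return 20.0 * image_width / 1920.0
        return float(self.exclude_px)


_INVALID = TriangulationResult(None, 0, float("nan"), frozenset())


#: denominator-reweighting passes of the linear solve; two suffice for
#: the solution to agree with the geometric (reprojection-error)
#: optimum far tighter than the pixel noise warrants
N_REFINE_PASSES = 2


def _solve(cams: dict[str, CameraDLT], obs: dict[str, np.ndarray], weights: dict[str, float]):
    """Stacked weighted linear solve over the given cameras.

    The algebraic residual of each equation equals the reprojection
    error times that camera's projective denominator, so after the
    first solve each camera's equations are re-scaled by its current
    denominator estimate; this removes the depth-dependent implicit
    weighting of the plain algebraic solution.
    """
    ids = list(obs)
    A = np.zeros((2 * len(ids), 3))
    b = np.empty(2 * len(ids))
    den = {cid: 1.0 for cid in ids}
    x = None
    for _ in range(N_REFINE_PASSES + 1):
        for i, cid in enumerate(ids):
            L = cams[cid].L
            u, v = obs[cid][0], obs[cid][1]
            w = weights[cid] / den[cid]
            A[2 * i] = w * np.array([u * L[8] - L[0], u * L[9] - L[1], u * L[10] - L[2]])
            A[2 * i + 1] = w * np.array([v * L[8] - L[4], v * L[9] - L[5], v * L[10] - L[6]])
            b[2 * i] = w * (L[3] - u)
            b[2 * i + 1] = w * (L[7] - v)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        den = {cid: abs(float(x @ cams[cid].L[8:11] + 1.0)) or 1.0 for cid in ids}
    return x


def _reprojection_errors(cams, obs, point) -> dict[str, float]:
    errs = {}
    for cid, uv in obs.items():
        pred = project_many(cams[cid], point.reshape(1, 3))[0]
        errs[cid] = float(np.linalg.norm(pred - uv[:2]))
    return errs


def triangulate(
    cams: dict[str, CameraDLT],
    obs: dict[str, np.ndarray],
    conf_min: float = 0.1,
    weight_by_confidence: bool = True,
    exclude_px: float | None = None,
) -> TriangulationResult:
    """Triangulate one keypoint from per-camera observations.

    ``obs`` maps camera_id to (u, v, confidence). Cameras below
    ``conf_min`` are dropped; if fewer than two remain the result is
    invalid. With ``exclude_px`` set and >= 3 usable cameras, cameras
    with anomalous reprojection residuals are excluded first.
    """
    usable = {
        cid: np.asarray(o, dtype=float)
        for cid, o in obs.items()
        if cid in cams and np.asarray(o, dtype=float)[2] >= conf_min
    }
    if len(usable) < 2:
        return _INVALID
    if exclude_px is not None and len(usable) >= 3:
        usable = exclude_outlier_cameras(
            cams, usable, exclude_px, weight_by_confidence=weight_by_confidence
        )
    weights = {
        cid: (float(o[2]) if weight_by_confidence else 1.0) for cid, o in usable.items()
    }
    point = _solve(cams, usable, weights)
    errs = _reprojection_errors(cams, usable, point)
    rms = float(np.sqrt(np.mean([e**2 for e in errs.values()])))
    return TriangulationResult(point, len(usable), rms, frozenset(usable))


def exclude_outlier_cameras(
    cams: dict[str, CameraDLT],
    obs: dict[str, np.ndarray],
    reproj_threshold_px: float,
    weight_by_confidence: bool = True,
) -> dict[str, np.ndarray]:
    """Iteratively drop the camera with the largest reprojection
    residual while it exceeds the threshold and >= 2 cameras remain.

    Deterministic: residual ties break by camera-id order.
    """
    current = dict(obs)
    while len(current) > 2:
        weights = {
            cid: (float(o[2]) if weight_by_confidence else 1.0)
            for cid, o in current.items()
        }
        point = _solve(cams, current, weights)
        errs = _reprojection_errors(cams, current, point)
        worst = max(sorted(errs), key=lambda cid: errs[cid])
        if errs[worst] > reproj_threshold_px:
            del current[worst]
        else:
            break
    return current


def reconstruct_sequence(
    streams: dict[str, Sequence[PoseFrame2D]],
    cams: dict[str, CameraDLT],
    params: ReconstructionParams | None = None,
    frame_rate: float = 1.0,
) -> Trajectory3D:
    """Triangulate every keypoint of every frame of aligned streams.

    Streams must be equal-length (run :func:`~mocapkit.synchronization.
    align_streams` first). Keypoints observed by fewer than two cameras
    above the confidence gate are marked invalid.
    """
    params = params or ReconstructionParams()
    lengths = {cid: len(s) for cid, s in streams.items()}
    if len(set(lengths.values())) != 1:
        raise LengthError(f"streams are not aligned: lengths {lengths}")
    n_frames = next(iter(lengths.values()))

    width = max(c.image_width for c in cams.values())
    exclude_px = params.resolved_exclude_px(width)

    data = np.zeros((n_frames, N_KEYPOINTS, 3))
    valid = np.zeros((n_frames, N_KEYPOINTS), dtype=bool)
    cam_ids = list(streams)
    stacked = {cid: np.stack([f.keypoints for f in streams[cid]]) for cid in cam_ids}
    for t in range(n_frames):
        for k in range(N_KEYPOINTS):
            obs = {cid: stacked[cid][t, k] for cid in cam_ids}
            res = triangulate(
                cams,
                obs,
                conf_min=params.conf_min,
                weight_by_confidence=params.weight_by_confidence,
                exclude_px=exclude_px,
            )
            if res.valid:
                data[t, k] = res.point
                valid[t, k] = True
    return Trajectory3D(data, valid, frame_rate, list(KEYPOINT_NAMES))
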