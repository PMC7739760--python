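"""Direct linear transformation (DLT) camera calibration.

Each camera is modelled by the classic 11-parameter DLT: with world
point (X, Y, Z) in mm and image point (u, v) in pixels,

    u = (L1 X + L2 Y + L3 Z + L4)  / (L9 X + L10 Y + L11 Z + 1)
    v = (L5 X + L6 Y + L7 Z + L8)  / (L9 X + L10 Y + L11 Z + 1)

i.e. a 3x4 projective matrix whose bottom-right entry is fixed to 1.
Calibration solves the inhomogeneous linear least-squares system formed
by the two observation equations each surveyed control point
contributes. No lens-distortion terms are modelled.

For numerical conditioning the world and image coordinates are centred
and isotropically scaled before solving, and the similarity transforms
are folded back into the returned coefficients afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    ConfigError,
    DegenerateGeometryError,
    InsufficientDataError,
    ParseError,
)

__all__ = [
    "ControlPoint",
    "CameraDLT",
    "dlt_calibrate",
    "project",
    "project_many",
    "read_control_points",
    "write_control_points",
    "read_calibration",
    "write_calibration",
]

#: ratio of smallest to largest singular value of the centred world
#: coordinates below which the control points are declared coplanar
COPLANARITY_TOL = 1e-6

#: |projection denominator| below this (relative to 1) is degenerate
DENOMINATOR_TOL = 1e-9


@dataclass
class ControlPoint:
    """A surveyed calibration point: known world position plus its
    observed pixel position in each camera that saw it."""

    name: str
    world: np.ndarray  # (3,) mm
    observations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.world = np.asarray(self.world, dtype=float).reshape(3)


@dataclass
class CameraDLT:
    """A calibrated camera: 11 DLT coefficients (the implicit 12th is
    1), image dimensions, and the calibration's RMS reprojection error
    in pixels."""

    camera_id: str
    L: np.ndarray  # (11,)
    image_width: int = 1920
    image_height: int = 1080
    rms_reprojection: float = 0.0

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float).reshape(11)

    @property
    def matrix(self) -> np.ndarray:
        """The 3x4 projective matrix with bottom-right entry 1."""
        P = np.empty((3, 4))
        P[0] = self.L[0:4]
        P[1] = self.L[4:8]
        P[2, :3] = self.L[8:11]
        P[2, 3] = 1.0
        return P


def _check_not_coplanar(world: np.ndarray) -> None:
    centred = world - world.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[0] == 0 or s[-1] < COPLANARITY_TOL * s[0]:
        raise DegenerateGeometryError(
            "control points are coplanar (or collinear); the 11-parameter "
            "DLT needs points spanning three dimensions"
        )


def dlt_calibrate(
    points: Sequence[ControlPoint],
    camera_id: str,
    image_size: tuple[int, int] = (1920, 1080),
) -> CameraDLT:
    """Estimate a camera's 11 DLT coefficients from >= 6 control points.

    Solves the stacked observation equations by linear least squares.
    Raises :class:`InsufficientDataError` with fewer than six observed
    points and :class:`DegenerateGeometryError` when the points are
    coplanar within tolerance.
    """
    seen = [p for p in points if camera_id in p.observations]
    if len(seen) < 6:
        raise InsufficientDataError(
            f"camera {camera_id!r}: {len(seen)} control points observed, need >= 6"
        )
    world = np.stack([p.world for p in seen])
    pix = np.array([p.observations[camera_id] for p in seen], dtype=float)
    _check_not_coplanar(world)

    # precondition: centre and scale world (RMS radius -> sqrt(3)) and
    # pixels (RMS radius -> sqrt(2))
    wc = world.mean(axis=0)
    ws = np.sqrt(3.0) / max(np.sqrt(np.mean(np.sum((world - wc) ** 2, axis=1))), 1e-12)
    pc = pix.mean(axis=0)
    ps = np.sqrt(2.0) / max(np.sqrt(np.mean(np.sum((pix - pc) ** 2, axis=1))), 1e-12)
    Wn = (world - wc) * ws
    Pn = (pix - pc) * ps

    n = len(seen)
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    X, Y, Z = Wn[:, 0], Wn[:, 1], Wn[:, 2]
    u, v = Pn[:, 0], Pn[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2], A[0::2, 3] = X, Y, Z, 1.0
    A[0::2, 8], A[0::2, 9], A[0::2, 10] = -u * X, -u * Y, -u * Z
    A[1::2, 4], A[1::2, 5], A[1::2, 6], A[1::2, 7] = X, Y, Z, 1.0
    A[1::2, 8], A[1::2, 9], A[1::2, 10] = -v * X, -v * Y, -v * Z
    b[0::2], b[1::2] = u, v
    Ln, *_ = np.linalg.lstsq(A, b, rcond=None)

    # fold normalization back: P = Tpix^-1 @ Pn @ Tworld, rescaled so P[2,3] = 1
    Pn_mat = np.empty((3, 4))
    Pn_mat[0] = Ln[0:4]
    Pn_mat[1] = Ln[4:8]
    Pn_mat[2, :3] = Ln[8:11]
    Pn_mat[2, 3] = 1.0
    Tw = np.eye(4)
    Tw[:3, :3] *= ws
    Tw[:3, 3] = -ws * wc
    Tp_inv = np.eye(3)
    Tp_inv[0, 0] = Tp_inv[1, 1] = 1.0 / ps
    Tp_inv[:2, 2] = pc
    P = Tp_inv @ Pn_mat @ Tw
    if abs(P[2, 3]) < DENOMINATOR_TOL:
        raise DegenerateGeometryError("degenerate DLT solution (P[2,3] ~ 0)")
    P = P / P[2, 3]
    L = np.concatenate([P[0], P[1], P[2, :3]])

    cam = CameraDLT(camera_id, L, image_size[0], image_size[1])
    reproj = project_many(cam, world)
    cam.rms_reprojection = float(np.sqrt(np.mean((reproj - pix) ** 2)))
    return cam


def project(cam: CameraDLT, p) -> tuple[float, float]:
    """Project one world point (mm) to pixel coordinates."""
    uv = project_many(cam, np.asarray(p, dtype=float).reshape(1, 3))
    return float(uv[0, 0]), float(uv[0, 1])


def project_many(cam: CameraDLT, pts: np.ndarray) -> np.ndarray:
    """Project (N, 3) world points to (N, 2) pixel coordinates."""
    pts = np.asarray(pts, dtype=float)
    L = cam.L
    den = pts @ L[8:11] + 1.0
    if np.any(np.abs(den) < DENOMINATOR_TOL):
        raise DegenerateGeometryError(
            f"camera {cam.camera_id!r}: projection denominator ~ 0 "
            "(point at or behind the camera plane)"
        )
    u = (pts @ L[0:3] + L[3]) / den
    v = (pts @ L[4:7] + L[7]) / den
    return np.stack([u, v], axis=1)


# ---------------------------------------------------------------------------
# Flat-text file formats
# ---------------------------------------------------------------------------


def write_control_points(path, points: Sequence[ControlPoint], camera_ids: Sequence[str]) -> None:
    """Control-point survey as CSV: name, world XYZ, then per-camera u, v
    (blank where a camera did not observe the point)."""
    cols = ["name", "X", "Y", "Z"]
    for cid in camera_ids:
        cols.extend([f"{cid}_u", f"{cid}_v"])
    lines = [",".join(cols)]
    for p in points:
        row = [p.name] + [f"{x:.6f}" for x in p.world]
        for cid in camera_ids:
            if cid in p.observations:
                u, v = p.observations[cid]
                row.extend([f"{u:.6f}", f"{v:.6f}"])
            else:
                row.extend(["", ""])
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_control_points(path) -> list[ControlPoint]:
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
        header = lines[0].split(",")
        cam_ids = [c[:-2] for c in header[4:] if c.endswith("_u")]
        points = []
        for line in lines[1:]:
            if not line.strip():
                continue
            cells = line.split(",")
            world = [float(x) for x in cells[1:4]]
            obs = {}
            for j, cid in enumerate(cam_ids):
                su, sv = cells[4 + 2 * j], cells[5 + 2 * j]
                if su.strip() and sv.strip():
                    obs[cid] = (float(su), float(sv))
            points.append(ControlPoint(cells[0], world, obs))
        return points
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed control-point file ({exc})") from exc


def write_calibration(path, cams: Sequence[CameraDLT]) -> None:
    """Calibration file: one record per camera — id, the 11 coefficients,
    image size, RMS reprojection error."""
    lines = ["camera_id,L1,L2,L3,L4,L5,L6,L7,L8,L9,L10,L11,width,height,rms_px"]
    for cam in cams:
        coeffs = ",".join(f"{x:.12g}" for x in cam.L)
        lines.append(
            f"{cam.camera_id},{coeffs},{cam.image_width},{cam.image_height},"
            f"{cam.rms_reprojection:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path) -> dict[str, CameraDLT]:
    path = Path(path)
    try:
        lines = Path(path).read_text().splitlines()
        cams = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            cells = line.split(",")
            cid = cells[0]
            L = [float(x) for x in cells[1:12]]
            cams[cid] = CameraDLT(
                cid, L, int(cells[12]), int(cells[13]), float(cells[14])
            )
        if not cams:
            raise ValueError("no camera records")
        return cams
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed calibration file ({exc})") from exc
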