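"""Marker-based reference joint centres.

The markerless output is validated against joint centres derived from
reflective-marker trajectories: elbow, wrist, knee and ankle centres are
the midpoints of their lateral and medial markers, shoulder centres the
midpoints of the anterior and posterior shoulder markers, and hip joint
centres come from the Harrington regression in a pelvis anatomical frame
built from the ASIS and PSIS markers.

Pelvis frame convention (stated explicitly because variants exist):
origin at mid-ASIS; the mediolateral axis points from the left to the
right ASIS; the anterior axis points from mid-PSIS toward mid-ASIS,
orthogonalized against the mediolateral axis; the superior axis
completes the right-handed triad. Pelvis width PW is the inter-ASIS
distance, pelvis depth PD the mid-ASIS-to-mid-PSIS distance, both in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cleaning import FilterSpec, butter_zero_lag, residual_analysis_cutoff
from .exceptions import DegenerateGeometryError, LengthError, MissingMarkerError
from .formats_io import Trajectory3D

__all__ = [
    "MarkerSet",
    "JointCenterSet",
    "HARRINGTON_COEFFS",
    "REQUIRED_MARKERS",
    "midpoint_center",
    "harrington_hjc",
    "build_reference",
]

#: Harrington et al. pelvis regression for the hip joint centre,
#: expressed in the pelvis frame in mm. Offsets from the mid-ASIS
#: origin: anterior-posterior = ap_pd * PD + ap_0 (negative =
#: posterior); inferior-superior = is_pw * PW + is_0 (negative =
#: inferior); mediolateral = +/-(ml_pw * PW + ml_0) (+ toward the
#: right). PW = pelvis width, PD = pelvis depth.
HARRINGTON_COEFFS = {
    "ap_pd": -0.24,
    "ap_0": -9.9,
    "is_pw": -0.30,
    "is_0": -10.9,
    "ml_pw": 0.33,
    "ml_0": 7.3,
}

#: Markers the six evaluated joints need (of the full-body set only
#: these are required here).
REQUIRED_MARKERS = tuple(
    [f"{s}_shoulder_{ap}" for s in "rl" for ap in ("anterior", "posterior")]
    + [
        f"{s}_{j}_{lm}"
        for s in "rl"
        for j in ("elbow", "wrist", "knee", "ankle")
        for lm in ("lateral", "medial")
    ]
    + ["r_asis", "l_asis", "r_psis", "l_psis"]
)

#: Joint labels of a complete reference set.
JOINTS = tuple(
    f"{s}_{j}" for s in "rl" for j in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle")
)


@dataclass
class MarkerSet:
    """Named reference marker trajectories at a common rate.

    ``markers`` maps marker name to an (T, 3) mm series; all series
    share length and timebase.
    """

    markers: dict[str, np.ndarray]
    frame_rate: float

    def __post_init__(self):
        lengths = set()
        cleaned = {}
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r}: expected (T, 3), got {arr.shape}")
            cleaned[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise LengthError(f"marker series lengths differ: {sorted(lengths)}")
        self.markers = cleaned

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    def require(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.markers]
        if missing:
            raise MissingMarkerError(missing)

    def to_trajectory(self) -> Trajectory3D:
        names = sorted(self.markers)
        data = np.stack([self.markers[n] for n in names], axis=1)
        valid = np.ones(data.shape[:2], dtype=bool)
        return Trajectory3D(data, valid, self.frame_rate, names)

    @classmethod
    def from_trajectory(cls, traj: Trajectory3D, aliases: dict[str, str] | None = None):
        """Build from a trajectory file; ``aliases`` maps file column
        names to canonical marker names."""
        aliases = aliases or {}
        markers = {}
        for i, name in enumerate(traj.names):
            markers[aliases.get(name, name)] = traj.data[:, i, :]
        return cls(markers, traj.frame_rate)


@dataclass
class JointCenterSet:
    """Derived joint-centre series (mm), sharing the marker timebase."""

    joints: dict[str, np.ndarray]
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return next(iter(self.joints.values())).shape[0]

    def resampled(self, dst_rate: float) -> "JointCenterSet":
        from .synchronization import resample_spline

        return JointCenterSet(
            {k: resample_spline(v, self.frame_rate, dst_rate) for k, v in self.joints.items()},
            dst_rate,
        )


def midpoint_center(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Joint centre as the elementwise midpoint of two marker series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LengthError(f"marker series shapes differ: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def harrington_hjc(
    lasis: np.ndarray, rasis: np.ndarray, lpsis: np.ndarray, rpsis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Left and right hip joint centres by the Harrington regression.

    Builds the pelvis anatomical frame per frame, applies the regression
    offsets (functions of pelvis width and depth), and transforms back
    to world coordinates. Returns (left, right) series.
    """
    lasis, rasis, lpsis, rpsis = (
        np.asarray(x, dtype=float) for x in (lasis, rasis, lpsis, rpsis)
    )
    shapes = {x.shape for x in (lasis, rasis, lpsis, rpsis)}
    if len(shapes) > 1:
        raise LengthError(f"ASIS/PSIS series shapes differ: {shapes}")
    single = lasis.ndim == 1
    if single:
        lasis, rasis, lpsis, rpsis = (x[None, :] for x in (lasis, rasis, lpsis, rpsis))

    mid_asis = (lasis + rasis) / 2.0
    mid_psis = (lpsis + rpsis) / 2.0
    ml = rasis - lasis
    pw = np.linalg.norm(ml, axis=1)
    if np.any(pw < 1e-9):
        raise DegenerateGeometryError("inter-ASIS distance ~ 0")
    z_ml = ml / pw[:, None]
    ap_raw = mid_asis - mid_psis
    pd_ = np.linalg.norm(ap_raw, axis=1)
    ap_ortho = ap_raw - (np.sum(ap_raw * z_ml, axis=1)[:, None]) * z_ml
    ap_norm = np.linalg.norm(ap_ortho, axis=1)
    if np.any(ap_norm < 1e-9):
        raise DegenerateGeometryError(
            "pelvis markers collinear: anterior axis undefined"
        )
    x_ap = ap_ortho / ap_norm[:, None]
    y_sup = np.cross(z_ml, x_ap)

    c = HARRINGTON_COEFFS
    ap_off = c["ap_pd"] * pd_ + c["ap_0"]
    is_off = c["is_pw"] * pw + c["is_0"]
    ml_off = c["ml_pw"] * pw + c["ml_0"]

    base = mid_asis + ap_off[:, None] * x_ap + is_off[:, None] * y_sup
    right = base + ml_off[:, None] * z_ml
    left = base - ml_off[:, None] * z_ml
    if single:
        return left[0], right[0]
    return left, right


def build_reference(
    markers: MarkerSet, filter_spec: FilterSpec | None = None
) -> JointCenterSet:
    """Filter the marker series and derive all twelve joint centres.

    With ``filter_spec`` None the cutoff is selected by residual
    analysis on the marker series (median across markers and axes).
    Raises :class:`MissingMarkerError` naming any absent required
    marker. Deterministic: identical input gives bit-identical output.
    """
    markers.require(REQUIRED_MARKERS)
    if filter_spec is None:
        cutoffs = [
            residual_analysis_cutoff(markers.markers[name][:, axis], markers.frame_rate)
            for name in ("r_ankle_lateral", "l_ankle_lateral", "r_wrist_lateral", "r_asis")
            for axis in range(3)
        ]
        filter_spec = FilterSpec(float(np.median(cutoffs)), markers.frame_rate)
    filtered = {
        name: butter_zero_lag(series, filter_spec)
        for name, series in markers.markers.items()
    }

    joints: dict[str, np.ndarray] = {}
    for side in "rl":
        joints[f"{side}_shoulder"] = midpoint_center(
            filtered[f"{side}_shoulder_anterior"], filtered[f"{side}_shoulder_posterior"]
        )
        for j in ("elbow", "wrist", "knee", "ankle"):
            joints[f"{side}_{j}"] = midpoint_center(
                filtered[f"{side}_{j}_lateral"], filtered[f"{side}_{j}_medial"]
            )
    left_hjc, right_hjc = harrington_hjc(
        filtered["l_asis"], filtered["r_asis"], filtered["l_psis"], filtered["r_psis"]
    )
    joints["l_hip"] = left_hjc
    joints["r_hip"] = right_hjc
    return JointCenterSet(joints, markers.frame_rate)
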