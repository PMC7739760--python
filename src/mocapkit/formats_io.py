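"""Reading and writing every file the pipeline touches.

Covers the pose estimator's per-frame keypoint JSON layout, TRC and CSV
3D-trajectory exports, calibration files, control-point surveys, and
per-trial synchronization tables.

Conventions: image coordinates have their origin at the top-left corner,
u rightward and v downward (the pose estimator's native pixel frame);
world coordinates are millimetres; time is counted in frames internally
and in seconds in exports.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .body25 import KEYPOINT_NAMES, N_KEYPOINTS
from .exceptions import FrameGapError, LengthError, ParseError

__all__ = [
    "Keypoint2D",
    "PoseFrame2D",
    "Trajectory3D",
    "read_keypoint_file",
    "read_keypoint_dir",
    "write_keypoint_file",
    "write_keypoint_dir",
    "select_person",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class Keypoint2D:
    """One detected landmark: pixel position and detection confidence.

    A confidence of exactly 0 means "not detected"; u and v then carry
    no meaning.
    """

    u: float
    v: float
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class PoseFrame2D:
    """All 25 keypoints of one camera at one frame.

    ``keypoints`` is a float array of shape (25, 3): columns u, v,
    confidence, rows indexed by the BODY_25 map.
    """

    camera_id: str
    frame_index: int
    keypoints: np.ndarray

    def __post_init__(self):
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValueError(f"keypoints must be (25, 3), got {kp.shape}")
        self.keypoints = kp

    @property
    def confidences(self) -> np.ndarray:
        return self.keypoints[:, 2]

    def detected(self, conf_min: float = 0.0) -> np.ndarray:
        """Boolean mask of keypoints with confidence above ``conf_min``
        (strictly above zero when ``conf_min`` is 0)."""
        c = self.keypoints[:, 2]
        return c > conf_min if conf_min == 0.0 else c >= conf_min


@dataclass
class Trajectory3D:
    """Per-keypoint world-coordinate time series with a validity mask.

    ``data`` has shape (n_frames, n_points, 3) in mm; ``valid`` is a
    boolean (n_frames, n_points) mask — entries of ``data`` at invalid
    frames carry no numeric meaning. World axes follow the capture
    convention: X lateral/medial, Y anterior/posterior, Z
    inferior/superior.
    """

    data: np.ndarray
    valid: np.ndarray
    frame_rate: float
    names: Sequence[str] = field(default_factory=lambda: list(KEYPOINT_NAMES))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"data must be (T, K, 3), got {self.data.shape}")
        if self.valid.shape != self.data.shape[:2]:
            raise ValueError("valid mask shape mismatch")
        if len(self.names) != self.data.shape[1]:
            raise ValueError("names length mismatch")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.names = list(self.names)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Trajectory3D":
        return Trajectory3D(
            self.data.copy(), self.valid.copy(), self.frame_rate, list(self.names)
        )

    def point(self, name_or_index) -> np.ndarray:
        """Series (T, 3) of one keypoint, by name or index."""
        idx = (
            self.names.index(name_or_index)
            if isinstance(name_or_index, str)
            else int(name_or_index)
        )
        return self.data[:, idx, :]


# ---------------------------------------------------------------------------
# Keypoint JSON files (pose-estimator layout)
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)_keypoints\.json$")


def _frame_index_of(path: Path) -> int:
    m = _FRAME_RE.search(path.name)
    if m is None:
        raise ParseError(f"{path}: file name does not encode a frame index")
    return int(m.group(1))


def read_keypoint_file(path) -> list[np.ndarray]:
    """Parse one per-frame keypoint JSON file.

    Returns one (25, 3) array per detected person (possibly empty).
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
        people = doc["people"]
        out = []
        for person in people:
            flat = np.asarray(person["pose_keypoints_2d"], dtype=float)
            if flat.size != 3 * N_KEYPOINTS:
                raise KeyError("pose_keypoints_2d length")
            out.append(flat.reshape(N_KEYPOINTS, 3))
        return out
    except (OSError, json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed keypoint file ({exc})") from exc


def select_person(
    candidates: list[np.ndarray], previous: PoseFrame2D | None = None
) -> np.ndarray | None:
    """Resolve a multi-person frame to the tracked subject.

    Continuity first: with a previous frame, pick the candidate whose
    mean distance to the previous keypoints (over keypoints detected in
    both) is smallest. Without a previous frame — or when no keypoint is
    shared — fall back to the highest summed confidence. Ties break by
    candidate order. Returns None for an empty candidate list ("no
    person"); the caller emits an all-zero frame.
    """
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    if previous is not None:
        scores = []
        prev_kp = previous.keypoints
        for cand in candidates:
            both = (cand[:, 2] > 0) & (prev_kp[:, 2] > 0)
            if both.any():
                d = np.linalg.norm(cand[both, :2] - prev_kp[both, :2], axis=1)
                scores.append(float(d.mean()))
            else:
                scores.append(np.inf)
        if np.isfinite(min(scores)):
            return candidates[int(np.argmin(scores))]
    sums = [float(c[:, 2].sum()) for c in candidates]
    return candidates[int(np.argmax(sums))]


def read_keypoint_dir(path, camera_id: str) -> list[PoseFrame2D]:
    """Ingest a directory of per-frame keypoint files for one camera.

    Files are ordered by the frame number encoded in their names; the
    sequence must be gap-free or :class:`FrameGapError` is raised
    listing the missing indices. Frames with no detected person yield
    all-zero keypoints; multi-person frames are resolved by
    :func:`select_person`.
    """
    path = Path(path)
    files = sorted(path.glob("*_keypoints.json"), key=_frame_index_of)
    if not files:
        raise ParseError(f"{path}: no keypoint files found")
    indices = [_frame_index_of(f) for f in files]
    expected = range(indices[0], indices[0] + len(indices))
    if indices != list(expected):
        missing = sorted(set(expected) - set(indices))
        # extra/duplicate indices also surface here via the mismatch
        raise FrameGapError(camera_id, missing or indices)

    frames: list[PoseFrame2D] = []
    prev: PoseFrame2D | None = None
    for fpath, idx in zip(files, indices):
        candidates = read_keypoint_file(fpath)
        chosen = select_person(candidates, prev)
        if chosen is None:
            chosen = np.zeros((N_KEYPOINTS, 3))
        frame = PoseFrame2D(camera_id, idx, chosen)
        frames.append(frame)
        prev = frame
    return frames


def write_keypoint_file(path, people: Iterable[np.ndarray]) -> None:
    """Write one per-frame keypoint file in the pose-estimator layout."""
    doc = {
        "version": 1.3,
        "people": [
            {"pose_keypoints_2d": [round(float(x), 6) for x in np.asarray(p).ravel()]}
            for p in people
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_keypoint_dir(path, frames: Sequence[PoseFrame2D], prefix: str = "frame") -> None:
    """Write a sequence of frames as per-frame keypoint files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        fname = f"{prefix}_{frame.frame_index:012d}_keypoints.json"
        write_keypoint_file(path / fname, [frame.keypoints])


# ---------------------------------------------------------------------------
# Trajectory exports: TRC and CSV
# ---------------------------------------------------------------------------


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".trc":
        return "trc"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer trajectory format from {path}")


def write_trajectory(traj: Trajectory3D, path, fmt: str | None = None) -> None:
    """Export a trajectory as TRC (default, biomechanics-interoperable)
    or plain CSV. Invalid frames become blank cells in both dialects."""
    fmt = _infer_format(path, fmt)
    if fmt == "trc":
        _write_trc(traj, path)
    elif fmt == "csv":
        _write_csv(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str | None = None) -> Trajectory3D:
    """Read a trajectory previously written by :func:`write_trajectory`."""
    fmt = _infer_format(path, fmt)
    if fmt == "trc":
        return _read_trc(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _cell(x: float, valid: bool) -> str:
    return f"{x:.4f}" if valid else ""


def _write_trc(traj: Trajectory3D, path) -> None:
    rate = traj.frame_rate
    n, k = traj.n_frames, traj.n_points
    lines = []
    lines.append(f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}")
    lines.append(
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
        "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames"
    )
    lines.append(f"{rate:g}\t{rate:g}\t{n}\t{k}\tmm\t{rate:g}\t1\t{n}")
    header = ["Frame#", "Time"]
    for name in traj.names:
        header.extend([name, "", ""])
    lines.append("\t".join(header))
    axes = ["\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(k))]
    lines.append("\t\t" + axes[0])
    for t in range(n):
        row = [str(t + 1), f"{t / rate:.6f}"]
        for j in range(k):
            ok = bool(traj.valid[t, j])
            row.extend(_cell(traj.data[t, j, a], ok) for a in range(3))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_trc(path) -> Trajectory3D:
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
        meta = lines[2].split("\t")
        rate = float(meta[0])
        n_frames = int(meta[2])
        n_markers = int(meta[3])
        names_row = lines[3].split("\t")
        names = [names_row[2 + 3 * j] for j in range(n_markers)]
        data = np.zeros((n_frames, n_markers, 3))
        valid = np.zeros((n_frames, n_markers), dtype=bool)
        for t, line in enumerate(lines[5 : 5 + n_frames]):
            cells = line.split("\t")
            for j in range(n_markers):
                triplet = cells[2 + 3 * j : 5 + 3 * j]
                if all(c.strip() for c in triplet):
                    data[t, j] = [float(c) for c in triplet]
                    valid[t, j] = True
        return Trajectory3D(data, valid, rate, names)
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed TRC file ({exc})") from exc


def _write_csv(traj: Trajectory3D, path) -> None:
    rate = traj.frame_rate
    cols = ["frame", "time", "frame_rate"]
    for name in traj.names:
        cols.extend([f"{name}_X", f"{name}_Y", f"{name}_Z"])
    lines = [",".join(cols)]
    for t in range(traj.n_frames):
        row = [str(t), f"{t / rate:.6f}", f"{rate:g}" if t == 0 else ""]
        for j in range(traj.n_points):
            ok = bool(traj.valid[t, j])
            row.extend(_cell(traj.data[t, j, a], ok) for a in range(3))
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_csv(path) -> Trajectory3D:
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
        cols = lines[0].split(",")
        names = [c[:-2] for c in cols[3:] if c.endswith("_X")]
        k = len(names)
        rows = lines[1:]
        rate = float(rows[0].split(",")[2])
        n = len(rows)
        data = np.zeros((n, k, 3))
        valid = np.zeros((n, k), dtype=bool)
        for t, line in enumerate(rows):
            cells = line.split(",")
            for j in range(k):
                triplet = cells[3 + 3 * j : 6 + 3 * j]
                if all(c.strip() for c in triplet):
                    data[t, j] = [float(c) for c in triplet]
                    valid[t, j] = True
        return Trajectory3D(data, valid, rate, names)
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed trajectory CSV ({exc})") from exc


def streams_to_arrays(streams: dict[str, Sequence[PoseFrame2D]]) -> dict[str, np.ndarray]:
    """Stack each camera's frame sequence into a (T, 25, 3) array."""
    out = {}
    lengths = {cid: len(frames) for cid, frames in streams.items()}
    if len(set(lengths.values())) > 1:
        raise LengthError(f"streams have unequal lengths: {lengths}")
    for cid, frames in streams.items():
        out[cid] = np.stack([f.keypoints for f in frames])
    return out
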