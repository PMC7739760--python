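"""Accuracy evaluation of markerless against marker-based trajectories.

The accuracy statistic is the mean absolute error (MAE) between the two
position series over a task-specific analysis window, per joint and per
world axis, in mm:

    MAE = (1/n) * sum_i |x_m,i - x_o,i|

where x_m is the marker-based and x_o the markerless estimate. Reports
are laid out joint x axis by task x condition, and summarized as the
fraction of cells under/over accuracy thresholds.

A packaged survey of 108 published MAE values from a five-camera
markerless-versus-optical validation experiment
(``data/published_mae_survey.csv``) is included to exercise the
threshold summary on real numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .body25 import RIGHT_JOINT_KEYPOINTS
from .exceptions import ConfigError, LengthError
from .formats_io import Trajectory3D
from .reference_kinematics import JointCenterSet

__all__ = [
    "AnalysisWindow",
    "MAEReport",
    "mae",
    "mae_report",
    "summarize_thresholds",
    "load_published_mae_survey",
    "read_windows_file",
]

AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class AnalysisWindow:
    """A task-specific analysis interval in frames (inclusive bounds).

    Window events (heel contacts, toe-off, arm-swing end) are inputs
    defined observationally per trial, not computed here.
    """

    start_frame: int
    end_frame: int
    task: str
    condition: str

    def __post_init__(self):
        if self.start_frame >= self.end_frame:
            raise ConfigError(
                f"window start {self.start_frame} must precede end {self.end_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class MAEReport:
    """Per-joint, per-axis MAE table.

    ``table`` is tidy: columns joint, axis, task, condition, mae_mm,
    n_frames. :meth:`pivot` gives the joint x axis by task x condition
    layout.
    """

    table: pd.DataFrame

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot_table(
            index=["joint", "axis"],
            columns=["task", "condition"],
            values="mae_mm",
            sort=False,
        )

    @property
    def values(self) -> np.ndarray:
        return self.table["mae_mm"].to_numpy()


def mae(xm: np.ndarray, xo: np.ndarray) -> float:
    """Mean absolute error between two equal-length series (mm).

    Both series must be fully valid (no NaN) over the window: cleaning
    is expected to have removed gaps before evaluation.
    """
    xm = np.asarray(xm, dtype=float)
    xo = np.asarray(xo, dtype=float)
    if xm.shape != xo.shape:
        raise LengthError(f"series shapes differ: {xm.shape} vs {xo.shape}")
    if xm.size == 0:
        raise LengthError("empty series")
    if np.isnan(xm).any() or np.isnan(xo).any():
        raise ConfigError("invalid (NaN) frames inside the analysis window")
    return float(np.mean(np.abs(xm - xo)))


def mae_report(
    reference: JointCenterSet,
    markerless: Trajectory3D,
    windows: Sequence[AnalysisWindow],
    joint_map: Mapping[str, int] | None = None,
    side: str = "r",
) -> MAEReport:
    """MAE per window, joint, and axis.

    ``joint_map`` maps joint name to the markerless keypoint index; by
    default the six right-side joints. The reference must already be at
    the markerless frame rate and aligned (see synchronization).
    Windows with any invalid markerless frame raise, as do unmapped
    joints.
    """
    joint_map = dict(joint_map or RIGHT_JOINT_KEYPOINTS)
    rows = []
    for window in windows:
        s, e = window.start_frame, window.end_frame + 1
        if e > markerless.n_frames or e > reference.n_frames:
            raise ConfigError(
                f"window [{window.start_frame}, {window.end_frame}] outside "
                f"trajectory of {markerless.n_frames} frames"
            )
        for joint, kp in joint_map.items():
            ref_key = joint if joint in reference.joints else f"{side}_{joint}"
            if ref_key not in reference.joints:
                raise ConfigError(f"joint {joint!r} not present in reference set")
            if not markerless.valid[s:e, kp].all():
                raise ConfigError(
                    f"window [{window.start_frame}, {window.end_frame}]: keypoint "
                    f"{kp} has invalid frames; clean before evaluating"
                )
            ref_series = reference.joints[ref_key][s:e]
            test_series = markerless.data[s:e, kp, :]
            for a, axis in enumerate(AXES):
                rows.append(
                    {
                        "joint": joint,
                        "axis": axis,
                        "task": window.task,
                        "condition": window.condition,
                        "mae_mm": mae(ref_series[:, a], test_series[:, a]),
                        "n_frames": window.n_frames,
                    }
                )
    return MAEReport(pd.DataFrame(rows))


def summarize_thresholds(
    values: Sequence[float],
    below: Sequence[float] = (20.0, 30.0),
    above: Sequence[float] = (40.0,),
) -> dict[str, float]:
    """Fractions (as percentages) of MAE values strictly below / above
    accuracy thresholds, e.g. ``{"<20 mm": 47.2, "<30 mm": 80.6,
    ">40 mm": 10.2}``."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise LengthError("no MAE values to summarize")
    out: dict[str, float] = {}
    for thr in below:
        out[f"<{thr:g} mm"] = 100.0 * float(np.mean(values < thr))
    for thr in above:
        out[f">{thr:g} mm"] = 100.0 * float(np.mean(values > thr))
    return out


def load_published_mae_survey() -> pd.DataFrame:
    """The packaged 108-cell published MAE survey (six joints x three
    axes x three tasks x two camera conditions), columns joint, axis,
    task, condition, mae_mm."""
    with resources.files("mocapkit.data").joinpath("published_mae_survey.csv").open() as fh:
        return pd.read_csv(fh)


def read_windows_file(path) -> list[AnalysisWindow]:
    """Analysis windows from CSV with columns start_frame, end_frame,
    task, condition."""
    df = pd.read_csv(Path(path))
    return [
        AnalysisWindow(int(r.start_frame), int(r.end_frame), str(r.task), str(r.condition))
        for r in df.itertuples()
    ]
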