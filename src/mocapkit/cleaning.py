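"""Trajectory cleaning: left-right swap correction, temporal-continuity
outlier flagging, gap interpolation, and zero-lag low-pass filtering with
a residual-analysis cutoff.

Pose estimators that process each video frame independently produce two
characteristic failure modes: homologous left/right landmarks exchanged
for a run of frames, and isolated detections far from the true position.
Both are repaired here using only the temporal continuity of the 3D
trajectories, after which series are gap-filled and smoothed with the
zero-lag fourth-order Butterworth filter conventional in biomechanics
(achieved as a second-order filter run forward then backward, with the
cutoff pre-warped to compensate for the double pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .body25 import LEFT_RIGHT_PAIRS
from .exceptions import ConfigError, LengthError
from .formats_io import Trajectory3D

__all__ = [
    "FilterSpec",
    "SwapEvent",
    "correct_lr_swaps",
    "flag_temporal_outliers",
    "interpolate_gaps",
    "butter_zero_lag",
    "residual_analysis_cutoff",
    "clean_trajectory",
]

#: correction so the -3 dB point of the dual-pass (effective 4th-order)
#: filter lands at the requested cutoff: 1 / (2**0.5 - 1)**0.25
DUAL_PASS_CUTOFF_CORRECTION = 1.0 / (2.0 ** 0.5 - 1.0) ** 0.25  # ~1.2465


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag low-pass specification: effective 4th order at
    ``cutoff_hz`` (two 2nd-order passes)."""

    cutoff_hz: float
    frame_rate: float
    order: int = 4

    def __post_init__(self):
        if not (0.0 < self.cutoff_hz < self.frame_rate / 2.0):
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz outside (0, Nyquist={self.frame_rate / 2} Hz)"
            )
        if self.order != 4:
            raise ConfigError("only the effective 4th-order (dual 2nd-order pass) filter is provided")


@dataclass(frozen=True)
class SwapEvent:
    """A frame where a homologous pair's labels were exchanged."""

    frame_index: int
    keypoint_pair: tuple[int, int]  # (left id, right id)
    applied: bool = True


def correct_lr_swaps(
    traj: Trajectory3D, pairs=LEFT_RIGHT_PAIRS
) -> tuple[Trajectory3D, list[SwapEvent]]:
    """Undo left-right label interchange using temporal continuity.

    For every homologous pair and every frame (in time order), the two
    labels are exchanged when doing so strictly reduces the summed
    displacement of both members from their last valid positions.
    Continuity alone fixes labels only up to one global flip per pair
    (an early swap can make the wrong labelling look continuous), so a
    final majority vote flips any pair the greedy pass swapped on more
    than half of its decided frames — the estimator is assumed right
    more often than wrong. The operation permutes labels only (the
    multiset of positions per frame is unchanged) and is idempotent.

    Frames where either member is invalid are skipped. Returns the
    corrected trajectory and the list of applied swap events.
    """
    if int(traj.valid.any(axis=1).sum()) < 2:
        raise LengthError("need at least two valid frames to correct swaps")
    out = traj.copy()
    events: list[SwapEvent] = []
    for left, right in pairs:
        dl = out.data[:, left, :]
        dr = out.data[:, right, :]
        vl = out.valid[:, left]
        vr = out.valid[:, right]
        last_l = last_r = None
        swapped = np.zeros(out.n_frames, dtype=bool)
        decided = 0
        for t in range(out.n_frames):
            if not (vl[t] and vr[t]):
                # keep continuity anchored through one-sided frames
                if vl[t] and last_l is not None:
                    last_l = dl[t].copy()
                if vr[t] and last_r is not None:
                    last_r = dr[t].copy()
                continue
            if last_l is None:
                last_l, last_r = dl[t].copy(), dr[t].copy()
                continue
            decided += 1
            d_keep = np.linalg.norm(dl[t] - last_l) + np.linalg.norm(dr[t] - last_r)
            d_swap = np.linalg.norm(dl[t] - last_r) + np.linalg.norm(dr[t] - last_l)
            if d_swap < d_keep:
                dl[t], dr[t] = dr[t].copy(), dl[t].copy()
                swapped[t] = True
            last_l, last_r = dl[t].copy(), dr[t].copy()
        if decided > 0 and swapped.sum() > decided / 2:
            # global flip: exchange the two label series wholesale
            out.data[:, [left, right], :] = out.data[:, [right, left], :]
            out.valid[:, [left, right]] = out.valid[:, [right, left]]
            swapped = ~swapped & vl & vr  # frames whose labels now differ from input
        for t in np.flatnonzero(swapped):
            events.append(SwapEvent(int(t), (left, right)))
    events.sort(key=lambda e: (e.frame_index, e.keypoint_pair))
    return out, events


def flag_temporal_outliers(
    series: np.ndarray,
    valid: np.ndarray,
    vmax: float,
    max_spike_frames: int = 3,
) -> np.ndarray:
    """Flag isolated spikes that break temporal continuity.

    A valid frame is flagged when its displacement from the last
    accepted frame exceeds ``vmax`` mm per elapsed frame AND skipping it
    (up to ``max_spike_frames`` consecutive frames) restores continuity
    — i.e. some later valid frame lies within ``vmax`` per frame of the
    last accepted one. A sustained step is genuine signal and is never
    flagged. Returns a boolean mask of flagged frames.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float).T).T  # (T,) -> (T,1)
    valid = np.asarray(valid, dtype=bool)
    n = series.shape[0]
    flags = np.zeros(n, dtype=bool)
    valid_idx = np.flatnonzero(valid)
    if valid_idx.size < 3:
        return flags
    ref = valid_idx[0]
    i = 1
    while i < valid_idx.size:
        t = valid_idx[i]
        disp = np.linalg.norm(series[t] - series[ref])
        if disp <= vmax * (t - ref):
            ref = t
            i += 1
            continue
        # candidate spike run starting at t: look ahead for a frame that
        # restores continuity with the reference
        healed = None
        for j in range(i + 1, min(i + 1 + max_spike_frames, valid_idx.size)):
            nxt = valid_idx[j]
            if np.linalg.norm(series[nxt] - series[ref]) <= vmax * (nxt - ref):
                healed = j
                break
        if healed is None:
            ref = t  # sustained displacement: accept as signal
            i += 1
        else:
            flags[valid_idx[i:healed]] = True
            ref = valid_idx[healed]
            i = healed + 1
    return flags


def interpolate_gaps(
    series: np.ndarray,
    valid: np.ndarray,
    max_gap_frames: int = 24,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Cubic-spline fill of interior invalid runs of length
    <= ``max_gap_frames``.

    Leading/trailing invalid frames stay invalid; longer interior gaps
    are left unfilled and reported as (start, end) inclusive index
    pairs. Returns (filled series, updated validity mask, unfilled gaps).
    """
    series = np.asarray(series, dtype=float).copy()
    valid = np.asarray(valid, dtype=bool).copy()
    idx = np.flatnonzero(valid)
    unfilled: list[tuple[int, int]] = []
    if idx.size == 0:
        return series, valid, unfilled
    if idx.size == series.shape[0]:
        return series, valid, unfilled
    if idx.size >= 4:
        interp = CubicSpline(idx, series[idx], axis=0)
    else:
        # too few samples for a cubic: fall back to linear per column
        flat = series[idx].reshape(idx.size, -1)

        def interp(t, _flat=flat):
            cols = [np.interp(t, idx, _flat[:, j]) for j in range(_flat.shape[1])]
            return np.stack(cols, axis=-1).reshape((len(t),) + series.shape[1:])
    gaps = np.flatnonzero(np.diff(idx) > 1)
    for g in gaps:
        start, end = idx[g] + 1, idx[g + 1] - 1
        if end - start + 1 <= max_gap_frames:
            fill_t = np.arange(start, end + 1)
            series[start : end + 1] = interp(fill_t)
            valid[start : end + 1] = True
        else:
            unfilled.append((int(start), int(end)))
    return series, valid, unfilled


def butter_zero_lag(
    series: np.ndarray, spec: FilterSpec, correct_cutoff: bool = True
) -> np.ndarray:
    """Zero-lag low-pass filter: 2nd-order Butterworth forward +
    backward (net 4th order, zero phase), applied along axis 0.

    With ``correct_cutoff`` (the biomechanics convention) the design
    cutoff is pre-warped by ~1.2465 so the dual-pass -3 dB point lands
    at ``spec.cutoff_hz``; the design cutoff is clamped just below
    Nyquist when the correction would push it past.
    """
    series = np.asarray(series, dtype=float)
    nyq = spec.frame_rate / 2.0
    fc = spec.cutoff_hz * (DUAL_PASS_CUTOFF_CORRECTION if correct_cutoff else 1.0)
    fc = min(fc, 0.995 * nyq)
    b, a = butter(2, fc / nyq)
    padlen = min(series.shape[0] - 1, max(9, int(3 * spec.frame_rate / spec.cutoff_hz)))
    return filtfilt(b, a, series, axis=0, padtype="odd", padlen=padlen)


def residual_analysis_cutoff(
    series: np.ndarray,
    frame_rate: float,
    grid: np.ndarray | None = None,
    noise_band: tuple[float, float] = (0.6, 0.9),
) -> float:
    """Select a low-pass cutoff by residual analysis (Winter's method).

    For each candidate cutoff fc the residual R(fc) is the RMS
    difference between the raw and zero-lag-filtered series. At high fc
    the residual is dominated by noise and falls linearly; a straight
    line fitted over the ``noise_band`` fraction of Nyquist and
    extrapolated to fc = 0 estimates the noise amplitude ``a``. The
    selected cutoff is the smallest candidate with R(fc) <= a — the
    point where distortion of signal balances passed noise — or the
    largest candidate if the residual never reaches the noise line
    (effectively noise-free data).

    The default grid runs from 0.5 Hz to 0.9 x Nyquist in 0.5 Hz steps.
    """
    series = np.asarray(series, dtype=float)
    nyq = frame_rate / 2.0
    if grid is None:
        grid = np.arange(0.5, 0.9 * nyq + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3 or np.any(grid <= 0) or np.any(grid >= nyq):
        raise ConfigError("cutoff grid must have >= 3 candidates inside (0, Nyquist)")
    R = np.empty(grid.size)
    for i, fc in enumerate(grid):
        filtered = butter_zero_lag(series, FilterSpec(fc, frame_rate))
        R[i] = np.sqrt(np.mean((series - filtered) ** 2))
    lo, hi = noise_band
    band = (grid >= lo * nyq) & (grid <= hi * nyq)
    if band.sum() < 3:
        raise ConfigError(
            f"noise band {noise_band} of Nyquist contains {int(band.sum())} grid "
            "points; need >= 3 for the linear fit"
        )
    slope, intercept = np.polyfit(grid[band], R[band], 1)
    a = intercept
    below = np.flatnonzero(R <= a)
    return float(grid[below[0]]) if below.size else float(grid[-1])


def clean_trajectory(
    traj: Trajectory3D,
    swap_correct: bool = True,
    outlier_vmax: float | None = "auto",
    max_gap_frames: int = 24,
    cutoff_hz: float | None = None,
    pairs=LEFT_RIGHT_PAIRS,
) -> tuple[Trajectory3D, dict]:
    """Full cleaning pass: swap correction -> outlier flagging -> gap
    interpolation -> zero-lag filtering.

    ``outlier_vmax`` defaults to 40 mm/frame at 120 Hz, scaled inversely
    with the frame period for other rates. ``cutoff_hz`` None selects
    the cutoff per keypoint-axis by residual analysis and applies the
    median across series (one cutoff for the whole trajectory, as is
    conventional). Returns the cleaned trajectory and a report dict.
    """
    report: dict = {}
    out = traj.copy()
    if swap_correct:
        out, events = correct_lr_swaps(out, pairs=pairs)
        report["swap_events"] = events
    if outlier_vmax is not None:
        if outlier_vmax == "auto":
            outlier_vmax = 40.0 * traj.frame_rate / 120.0
        n_flagged = 0
        for k in range(out.n_points):
            flags = flag_temporal_outliers(out.data[:, k, :], out.valid[:, k], outlier_vmax)
            out.valid[flags, k] = False
            n_flagged += int(flags.sum())
        report["outliers_flagged"] = n_flagged
    unfilled_total = []
    for k in range(out.n_points):
        filled, newvalid, unfilled = interpolate_gaps(
            out.data[:, k, :], out.valid[:, k], max_gap_frames
        )
        out.data[:, k, :] = filled
        out.valid[:, k] = newvalid
        unfilled_total.extend((k, s, e) for s, e in unfilled)
    report["unfilled_gaps"] = unfilled_total

    if cutoff_hz is None:
        cutoffs = []
        for k in range(out.n_points):
            mask = out.valid[:, k]
            if mask.sum() < 100:
                continue
            run = _longest_valid_run(mask)
            for axis in range(3):
                cutoffs.append(
                    residual_analysis_cutoff(
                        out.data[run, k, axis], out.frame_rate
                    )
                )
        if not cutoffs:
            raise LengthError("no keypoint series long enough for residual analysis")
        cutoff_hz = float(np.median(cutoffs))
    report["cutoff_hz"] = cutoff_hz
    spec = FilterSpec(cutoff_hz, out.frame_rate)
    for k in range(out.n_points):
        mask = out.valid[:, k]
        run = _longest_valid_run(mask)
        if run.stop - run.start > 18:
            out.data[run, k, :] = butter_zero_lag(out.data[run, k, :], spec)
    return out, report


def _longest_valid_run(mask: np.ndarray) -> slice:
    """Largest contiguous True run of a boolean mask, as a slice."""
    best = slice(0, 0)
    start = None
    for i, ok in enumerate(list(mask) + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start > best.stop - best.start:
                best = slice(start, i)
            start = None
    return best
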