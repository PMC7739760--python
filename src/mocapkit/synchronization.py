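"""Multi-camera stream alignment and frame-rate resampling.

Cameras are synchronized on a shared light event whose frame index was
identified per camera. Alignment is integer-frame only: after trimming,
frame i of every stream refers to the same instant up to half a frame
period of residual offset, which is an irreducible comparison error of
the method. Reference (marker-based) data recorded at a higher rate is
brought to the markerless rate by cubic-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import ConfigError, LengthError

__all__ = ["SyncInfo", "align_streams", "resample_spline", "read_sync_file", "write_sync_file"]


@dataclass
class SyncInfo:
    """Per-trial synchronization table.

    ``event_frames`` maps camera_id to the frame index of the light
    switch-on; ``which_event`` records whether the shared event is the
    one before ("start") or after ("end") the trial — metadata for
    provenance, the trimming arithmetic is identical.
    """

    event_frames: dict[str, int]
    frame_rate: float
    which_event: str = "start"
    frame_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.which_event not in ("start", "end"):
            raise ConfigError(f"which_event must be start|end, got {self.which_event!r}")
        for cid, rate in self.frame_rates.items():
            if rate != self.frame_rate:
                raise ConfigError(
                    f"camera {cid!r} frame rate {rate} differs from trial rate "
                    f"{self.frame_rate}; streams must share one rate"
                )


def align_streams(streams: dict[str, Sequence], sync: SyncInfo) -> dict[str, list]:
    """Trim per-camera sequences so the sync event lands at the same
    index in every stream and all streams have equal length.

    The output spans the maximum common window around the event:
    ``min(frames before event)`` + ``min(frames at/after event)``
    frames, with the event at index ``min(frames before event)``.
    """
    if not streams:
        raise ConfigError("no streams to align")
    before, after = [], []
    for cid, frames in streams.items():
        if cid not in sync.event_frames:
            raise ConfigError(f"camera {cid!r} has no sync event frame")
        e = sync.event_frames[cid]
        n = len(frames)
        if not (0 <= e < n):
            raise ConfigError(
                f"camera {cid!r}: event frame {e} outside stream of length {n}"
            )
        before.append(e)
        after.append(n - e)
    span_before, span_after = min(before), min(after)
    out = {}
    for cid, frames in streams.items():
        e = sync.event_frames[cid]
        out[cid] = list(frames[e - span_before : e + span_after])
    return out


def resample_spline(
    series: np.ndarray, src_rate: float, dst_rate: float
) -> np.ndarray:
    """Resample a uniformly sampled series by cubic-spline interpolation.

    The series is treated as samples at t = k / src_rate; the output is
    the spline evaluated at t = k / dst_rate over the common support
    (no extrapolation). Not-a-knot boundary conditions. Works along
    axis 0 for multi-dimensional series. When ``dst_rate == src_rate``
    the input is returned unchanged.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 4:
        raise LengthError(f"series of length {n} too short to resample (need >= 4)")
    if dst_rate <= 0 or src_rate <= 0:
        raise ConfigError("rates must be positive")
    if src_rate < dst_rate:
        raise ConfigError(
            f"upsampling ({src_rate} -> {dst_rate} Hz) is not supported; "
            "the reference is downsampled to the markerless rate"
        )
    if dst_rate == src_rate:
        return series.copy()
    t_end = (n - 1) / src_rate
    t_src = np.arange(n) / src_rate
    n_dst = int(np.floor(t_end * dst_rate + 1e-9)) + 1
    t_dst = np.arange(n_dst) / dst_rate
    spline = CubicSpline(t_src, series, axis=0)
    return spline(t_dst)


def read_sync_file(path) -> SyncInfo:
    """Read a per-trial sync table: CSV with columns
    camera_id, event_frame, which_event, frame_rate."""
    lines = Path(path).read_text().splitlines()
    header = [c.strip() for c in lines[0].split(",")]
    idx = {name: header.index(name) for name in ("camera_id", "event_frame", "which_event", "frame_rate")}
    events, rates, which = {}, {}, set()
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(",")]
        cid = cells[idx["camera_id"]]
        events[cid] = int(cells[idx["event_frame"]])
        rates[cid] = float(cells[idx["frame_rate"]])
        which.add(cells[idx["which_event"]])
    if len(which) != 1:
        raise ConfigError(f"inconsistent which_event across cameras: {sorted(which)}")
    rate = next(iter(rates.values()))
    return SyncInfo(events, rate, which.pop(), frame_rates=rates)


def write_sync_file(path, sync: SyncInfo) -> None:
    lines = ["camera_id,event_frame,which_event,frame_rate"]
    for cid, e in sync.event_frames.items():
        lines.append(f"{cid},{e},{sync.which_event},{sync.frame_rate:g}")
    Path(path).write_text("\n".join(lines) + "\n")
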