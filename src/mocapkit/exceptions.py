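"""Exception hierarchy for mocapkit.

Every error raised on a user-facing path derives from :class:`MocapError`
so callers (and the CLI) can catch one type.
"""


class MocapError(Exception):
    """Base class for all mocapkit errors."""


class ParseError(MocapError):
    """A file could not be parsed; the message names the offending file."""


class FrameGapError(MocapError):
    """A keypoint stream has missing frame indices."""

    def __init__(self, camera_id, missing):
        self.camera_id = camera_id
        self.missing = list(missing)
        super().__init__(
            f"camera {camera_id!r}: missing frame indices {self.missing}"
        )


class ConfigError(MocapError):
    """Invalid configuration or parameter value."""


class LengthError(MocapError):
    """Series lengths are incompatible or a series is too short."""


class DegenerateGeometryError(MocapError):
    """Geometric input is degenerate (coplanar control points,
    collinear pelvis markers, near-zero projection denominator)."""


class InsufficientDataError(MocapError):
    """Too few observations to run an estimation."""


class MissingMarkerError(MocapError):
    """A required reference marker is absent; message lists the names."""

    def __init__(self, names):
        self.names = list(names)
        super().__init__(f"missing required markers: {', '.join(self.names)}")
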