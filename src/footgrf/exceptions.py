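"""Error types raised across the package."""


class FootGrfError(Exception):
    """Base class for all package errors."""


class FormatError(FootGrfError):
    """A marker or time-series file does not parse as the named standard."""


class MissingMarkerError(FootGrfError):
    """A marker required by the subject model is absent from a trial."""

    def __init__(self, marker: str, context: str = ""):
        self.marker = marker
        msg = f"required marker {marker!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class CalibrationError(FootGrfError):
    """The static calibration trial is unusable (motion, duration, geometry)."""


class DegenerateFitError(FootGrfError):
    """A segment's marker cloud is collinear or too sparse for a rigid fit."""

    def __init__(self, segment: str, frame: int | None = None):
        self.segment = segment
        self.frame = frame
        where = f" at frame {frame}" if frame is not None else ""
        super().__init__(f"degenerate rigid fit for segment {segment!r}{where}")


class ParameterError(FootGrfError):
    """A numeric argument is out of its valid range."""


class PhaseError(FootGrfError):
    """An operation was called on frames of the wrong support phase."""


class GeometryError(FootGrfError):
    """A geometric precondition is violated (e.g. VPP below the ground COP)."""


class DimensionError(FootGrfError):
    """Array lengths or shapes of jointly-used inputs disagree."""
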