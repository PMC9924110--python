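"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ProtonWetError` so callers can
distinguish pipeline failures from programming errors.
"""


class ProtonWetError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(ProtonWetError, ValueError):
    """Invalid parameters or domain objects."""


class RangeNotFoundError(ProtonWetError):
    """The distal edge of a depth-dose curve does not cross the requested level."""


class RangeTruncationError(ProtonWetError):
    """The shifted distal falloff exits the detector span."""


class ResolutionError(ProtonWetError):
    """A geometric feature is not resolved by the voxel grid."""


class GeometryError(ProtonWetError):
    """Beam/structure geometry is inconsistent (e.g. beam ray misses the CTV)."""


class CalibrationError(ProtonWetError, ValueError):
    """Non-monotone or otherwise unusable calibration table."""


class ShapeMismatchError(ProtonWetError):
    """Mask and phantom grids do not agree."""


class MalformedFileError(ProtonWetError):
    """A file could not be parsed (bad header, wrong columns...)."""


class UndefinedTestError(ProtonWetError):
    """A statistical test is undefined for the given data (e.g. all-zero differences)."""


class StageError(ProtonWetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
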