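"""Exception hierarchy for the gait pipeline."""


class GaitPoseError(Exception):
    """Base class for all gaitpose errors."""


class ParseError(GaitPoseError):
    """A keypoint document could not be parsed."""


class SchemaError(GaitPoseError):
    """A table is missing required columns or rows disagree on schema."""


class MissingJointError(GaitPoseError):
    """A required joint has no detection (confidence 0)."""


class UndefinedAngleError(GaitPoseError):
    """An angle is undefined because a segment has zero length."""


class CalibrationError(GaitPoseError):
    """Standing calibration failed or is inconsistent with projections."""


class DomainError(GaitPoseError):
    """An input lies outside the validity domain of a kinematic formula."""


class InsufficientDataError(GaitPoseError):
    """Too few gait cycles (or frames) to compute the requested quantity."""
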