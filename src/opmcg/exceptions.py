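"""Exception hierarchy for the opmcg pipeline.

Errors distinguish bad arguments (programming/config mistakes), data-quality
failures (a scan that should be flagged and excluded, mirroring automatic
software rejection in clinical practice), and undefined geometric quantities.
"""


class OpmcgError(Exception):
    """Base class for all opmcg errors."""


class InvalidArgumentError(OpmcgError, ValueError):
    """An argument violates a documented precondition."""


class QualityError(OpmcgError):
    """A recording fails quality rules (too few beats, flat signal, ...)."""


class FiducialError(OpmcgError):
    """Fiducial points (R-peak, T-onset, T-peak) could not be located."""


class UndefinedAngleError(OpmcgError):
    """An angle is requested from a map or pole set where it is undefined."""


class MissingDataError(OpmcgError):
    """A required score or item is missing."""


class NotImputableError(MissingDataError):
    """All items of an exertional level are missing; imputation impossible."""


class NotTestableError(OpmcgError):
    """A statistical test cannot be formed (e.g. too few unique values)."""


class ScreeningEmptyError(OpmcgError):
    """Variance/correlation screening removed every feature."""


class FormatError(OpmcgError):
    """A feature-table or config file violates the expected layout."""
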