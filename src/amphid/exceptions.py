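"""Exception hierarchy for the amphid package."""


class AmphidError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AmphidError, ValueError):
    """Invalid user-supplied parameters or malformed input files."""


class InsufficientPointsError(ValidationError):
    """Fewer points than a geometric fit requires."""


class DegenerateGeometryError(ValidationError):
    """Point configuration does not determine the requested fit (e.g. collinear)."""


class EmptyCohortError(ValidationError):
    """No analyzable worms remain in a cohort."""


class DegenerateRegressionError(ValidationError):
    """Too few distinct ranks to fit a regression line."""


class NoRankError(ValidationError):
    """A dorso-ventral rank was requested for an unidentified neuron."""
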