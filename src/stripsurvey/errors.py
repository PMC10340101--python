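"""Exception hierarchy shared across the package.

Error families map onto distinct CLI exit codes: data/validation problems
(exit 2), model-fitting problems (exit 3), and I/O problems (exit 4).
"""


class StripSurveyError(Exception):
    """Base class for all package errors."""


class SchemaError(StripSurveyError):
    """A required column or field is missing or has the wrong type."""


class ValidationError(StripSurveyError):
    """A record violates a domain invariant (e.g. nonpositive length)."""


class ReferentialError(StripSurveyError):
    """A record references an unknown transect."""


class FitError(StripSurveyError):
    """A maximum-likelihood fit failed to converge."""


class NoInformationError(FitError):
    """The data carry no information about the parameter (e.g. no
    first-observer detections in a removal survey)."""


class BoundaryError(FitError):
    """The MLE lies on or beyond the boundary of the parameter space."""


class NumericalError(StripSurveyError):
    """A numerical routine (quadrature, matrix inversion) did not reach
    the requested tolerance."""
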