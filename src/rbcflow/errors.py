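"""Exception hierarchy shared across the pipeline stages."""


class RBCFlowError(Exception):
    """Base class for all rbcflow errors."""


class InvalidMeasurementError(RBCFlowError):
    """A physical measurement violates its preconditions (e.g. axis <= 0)."""


class ConventionViolationError(RBCFlowError):
    """Caller broke an ordering convention (e.g. major axis < minor axis)."""


class EmptyInputError(RBCFlowError):
    """An operation that needs data received none."""


class InvariantViolationError(RBCFlowError):
    """Input data breaks a domain invariant (e.g. elongation ratio < 1)."""


class InsufficientDataError(RBCFlowError):
    """Too few observations for the requested statistic."""


class DegenerateShapeError(RBCFlowError):
    """A connected component is too small or collinear to fit an ellipse."""


class DegenerateThresholdError(RBCFlowError):
    """Foreground thresholding cannot separate the image."""


class DegenerateFitError(RBCFlowError):
    """A regression predictor has zero variance."""


class CalibrationInfeasibleError(RBCFlowError):
    """No population model can satisfy the requested target profile."""


class PlacementFailureError(RBCFlowError):
    """Could not place cells without overlap within the retry budget."""


class MissingColumnError(RBCFlowError):
    """A required column (e.g. protein) is absent from a table."""


class ValidationError(RBCFlowError):
    """Configuration failed validation before any computation ran."""
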