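"""Exception hierarchy shared across the package."""


class RamanQCError(Exception):
    """Base class for all package errors."""


class FormatError(RamanQCError):
    """Malformed input file (ragged rows, duplicate ids, bad axis, ...)."""


class ParameterError(RamanQCError, ValueError):
    """Invalid user-supplied parameter."""


class ConfigurationError(RamanQCError):
    """Invalid generator / pipeline configuration."""


class InvalidMeasurementError(RamanQCError, ValueError):
    """Physically impossible gravimetric measurement."""


class DomainError(RamanQCError, ValueError):
    """Input outside the mathematical domain of an operation."""


class GroupingError(RamanQCError):
    """Replicate grouping key could not be resolved."""


class DegenerateSpectrumError(RamanQCError):
    """A spectrum with zero dynamic range cannot be min-max scaled."""


class NumericalError(RamanQCError):
    """Numerical failure (singular covariance etc.)."""


class ScreeningDegenerateError(RamanQCError):
    """Outlier screening flagged every sample."""


class EmptySelectionError(RamanQCError):
    """A variable selector returned no channels."""


class DegenerateTargetError(RamanQCError, ValueError):
    """Constant target vector cannot be regressed against."""


class DataError(RamanQCError, ValueError):
    """Inconsistent or non-finite data passed to a model or metric."""


class ArchitectureError(RamanQCError):
    """Network input is incompatible with the layer stack."""


class TrainingError(RamanQCError):
    """Optimisation diverged."""


class IncompatibilityError(RamanQCError):
    """Prediction input does not match the model's training axis."""


class LookupError_(RamanQCError, KeyError):
    """Requested attribute/model not present."""
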