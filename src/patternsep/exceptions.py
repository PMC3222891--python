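"""Exception hierarchy for the patternsep pipeline."""


class PatternsepError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PatternsepError, ValueError):
    """A parameter is outside its valid range or of the wrong kind."""


class InsufficientTrialsError(PatternsepError, ValueError):
    """Too few (accurate) trials to run the requested analysis."""


class DegenerateLabelsError(PatternsepError, ValueError):
    """Classifier training requires at least two distinct classes."""


class InvalidPairError(PatternsepError, ValueError):
    """A cross-classification pair must differ in exactly one design factor."""


class SingularDesignError(PatternsepError, ValueError):
    """The GLM design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class DegenerateInputError(PatternsepError, ValueError):
    """Input is numerically degenerate (e.g. zero residual variance)."""


class ZeroVarianceError(PatternsepError, ValueError):
    """A t statistic is undefined because the sample variance is zero."""


class InsufficientDataError(PatternsepError, ValueError):
    """Too few usable participants for a group-level test."""


class EmptyMaskError(PatternsepError, ValueError):
    """An ROI mask contains no voxels."""


class ShapeError(PatternsepError, ValueError):
    """Array shapes (or affines) of companion objects do not match."""


class ConfigError(PatternsepError, ValueError):
    """A run configuration is missing or has an invalid field."""
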