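"""Exception hierarchy shared across the package."""


class PatternRiskError(Exception):
    """Base class for all package errors."""


class SchemaError(PatternRiskError):
    """The risk-factor schema is malformed or a file does not match it."""


class ValidationDataError(PatternRiskError):
    """Input data violate a record-level invariant."""


class ConfigError(PatternRiskError):
    """A synthetic-scenario or tool configuration is invalid."""


class EncodingError(PatternRiskError):
    """A value cannot be encoded into design-matrix terms."""


class DegenerateOutcomeError(PatternRiskError):
    """Only one outcome class present; a logistic model cannot be fit."""


class SeparationError(PatternRiskError):
    """Perfect or quasi-perfect separation detected during fitting.

    ``terms`` names the coefficients that diverged.
    """

    def __init__(self, message, terms=()):
        super().__init__(message)
        self.terms = tuple(terms)


class InsufficientDataError(PatternRiskError):
    """Too few rows or events to fit a model for the requested pattern."""


class EnsembleEmptyError(PatternRiskError):
    """Every training cohort was skipped; no ensemble member survived."""


class CannotImputeError(PatternRiskError):
    """A factor has no observed values anywhere, so it cannot be imputed."""


class FamilyHistoryConsistencyError(ValidationDataError):
    """Second-degree prostate and first-degree breast family history must be
    jointly observed or jointly missing."""


class UnservedPatternError(PatternRiskError):
    """The pattern-model library has no usable model for the requested pattern.

    ``suggestion`` holds the nearest served sub-pattern, if any.
    """

    def __init__(self, message, suggestion=None):
        super().__init__(message)
        self.suggestion = suggestion


class LibraryLoadError(PatternRiskError):
    """A serialized pattern-model library could not be loaded."""
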