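"""Exception hierarchy.

Every validation failure in the package raises one of these, so callers can
distinguish malformed files (FormatError), semantically invalid content
(DesignError, ValueError subclasses) and bad parameters (ParameterError).
"""


class EpichainError(Exception):
    """Base class for all package errors."""


class FormatError(EpichainError):
    """A file or table does not match the documented dialect."""


class DesignError(EpichainError):
    """A study design violates the paired two-tissue layout."""


class MatrixValueError(EpichainError):
    """A matrix value violates its declared kind."""


class AnnotationError(EpichainError):
    """A probe or link is missing or inconsistent with the annotation."""


class ParameterError(EpichainError):
    """A parameter is outside its documented range."""


class NormalizationError(EpichainError):
    """Scaling-factor normalization cannot proceed for a sample."""


class DegreesOfFreedomError(EpichainError):
    """Too few patients to fit the model."""


class ConsistencyError(EpichainError):
    """Two tables that must share identifiers do not."""
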