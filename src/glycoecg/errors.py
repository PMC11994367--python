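"""Exception hierarchy.

All package-specific failures derive from :class:`GlycoECGError` so callers
can catch one base class at pipeline boundaries; parameter-validation
failures additionally derive from :class:`ValueError` to behave like the
standard library.
"""


class GlycoECGError(Exception):
    """Base class for all glycoecg errors."""


class EmptyInputError(GlycoECGError, ValueError):
    """An input file or array contained no usable data."""


class MalformedRecordError(GlycoECGError, ValueError):
    """An ECG text record violates the dialect (e.g. non-monotonic time)."""


class DialectError(GlycoECGError, ValueError):
    """An ECG text record is readable but outside the supported dialect
    (irregular sample spacing, index column without an expected rate...)."""


class SchemaError(GlycoECGError, ValueError):
    """A cohort table is missing required columns or has the wrong types."""


class ParameterError(GlycoECGError, ValueError):
    """A parameter is outside its documented domain."""


class DecompositionDepthError(GlycoECGError, ValueError):
    """Signal too short for the requested wavelet decomposition depth."""


class ConfigurationError(GlycoECGError, ValueError):
    """Unknown wavelet name, component label, or config value."""


class NoPeaksError(GlycoECGError, ValueError):
    """Peak detection ran on a constant (or all-zero) signal."""


class InsufficientDataError(GlycoECGError, ValueError):
    """Too few peaks/intervals for the requested statistic."""


class UndefinedCorrelationError(GlycoECGError, ValueError):
    """Pearson correlation requested against a constant array."""


class DegenerateTrainingError(GlycoECGError, ValueError):
    """Classifier training set does not contain two classes."""


class StratificationError(GlycoECGError, ValueError):
    """A class has too few rows for a stratified split."""


class InsufficientBeatsWarning(UserWarning):
    """Fewer than three beats detected; derived features are unreliable."""
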