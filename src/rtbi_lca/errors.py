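"""Exception hierarchy shared across the package."""


class RtbiLcaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RtbiLcaError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class ValidationError(RtbiLcaError, ValueError):
    """Input records failed schema or invariant validation."""


class ArgumentError(RtbiLcaError, ValueError):
    """An operation was called with an invalid argument."""


class EmptyInputError(ArgumentError):
    """An operation requiring non-empty input received none."""


class SchemaError(RtbiLcaError, ValueError):
    """Structured inputs (draws, pools) have mismatched shapes or names."""


class GridSizeError(ArgumentError):
    """A brute-force grid would exceed the documented size limit."""


class IdentifiabilityError(ArgumentError):
    """Sensitivity + specificity <= 1: the latent classes are not separable."""


class UndefinedValueError(ArgumentError):
    """A closed-form quantity has a zero denominator for these inputs."""


class DegenerateInputError(ArgumentError):
    """Input is degenerate for the requested diagnostic (e.g. zero variance)."""


class PipelineError(RtbiLcaError, RuntimeError):
    """A pipeline stage failed fatally; diagnostics attached."""
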