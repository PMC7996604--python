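"""Exception hierarchy shared across the package."""


class CrossfluidError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CrossfluidError):
    """A file does not conform to the expected dialect (missing columns, bad GMT line)."""


class IntegrityError(CrossfluidError):
    """Input violates a uniqueness or consistency invariant (duplicate keys, dimension mismatch)."""


class ParameterError(CrossfluidError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(CrossfluidError):
    """Fewer observations than the minimum required for the requested statistic."""


class DegenerateDesignError(CrossfluidError):
    """The regression design is singular (e.g. constant predictor)."""


class UndefinedCorrelationError(CrossfluidError):
    """Correlation is undefined (zero weighted variance in one of the variables)."""


class EmptyResultError(CrossfluidError):
    """An operation produced an empty result where at least one element is required."""
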