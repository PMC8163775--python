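"""Exception hierarchy for the mixsig pipeline."""


class MixsigError(Exception):
    """Base class for all package errors."""


class ConfigError(MixsigError):
    """A configuration object violates one of its invariants."""


class NormalizationError(MixsigError):
    """Raised when count normalization cannot proceed (e.g. all-zero controls)."""


class AssemblyError(MixsigError):
    """Raised when feature submatrices cannot be combined (sample-set mismatch)."""


class ScreeningError(MixsigError):
    """Raised on invalid screening input (e.g. single-class response)."""


class EvaluationError(MixsigError):
    """Raised when a metric is undefined on the given input."""


class EmptyModelError(MixsigError):
    """The final elastic-net fit returned no non-zero coefficients."""


class SurvivalError(MixsigError):
    """Raised on degenerate survival comparisons (e.g. a single group)."""
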