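"""Domain-specific error types.

All inherit from ValueError so callers that only care about "bad input"
can catch one base class, while the pipeline can label the failing stage.
"""


class LQRadError(ValueError):
    """Base class for all lqrad errors."""


class NormalizationError(LQRadError):
    """Control wells missing, empty, or with non-positive mean signal."""


class InsufficientDataError(LQRadError):
    """A stratum has too few distinct doses to identify the LQ parameters."""


class DegenerateFitError(LQRadError):
    """Zero response variance: goodness of fit is undefined."""


class UndefinedRatioError(LQRadError):
    """alpha/beta requested with beta = 0."""


class DesignError(LQRadError):
    """A simulation design violates its own invariants."""
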