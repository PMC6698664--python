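"""Exception hierarchy for oxkinetics.

Validation problems (bad inputs) are distinguished from fit failures
(well-formed data that the model cannot describe) and from inconclusive
analyses (data that end too early to call an outcome either way).
"""


class OxkineticsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OxkineticsError, ValueError):
    """Raised when input data or parameters violate a precondition."""


class FitFailureError(OxkineticsError, RuntimeError):
    """Raised when a fit is attempted but produces a nonsensical result
    (e.g. negative Schleif-plot slope). Distinct from a stalled call,
    which is a legitimate biological outcome, not an error."""


class InconclusiveGrowthError(OxkineticsError, RuntimeError):
    """Raised when a growth curve ends too soon after the stress to decide
    between recovery and non-recovery."""
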