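"""Exception hierarchy.

Validation/configuration problems (caller errors) and data problems
(malformed or uninformative input) are kept distinct so the CLI can map
them onto separate exit codes.
"""


class FabricMotionError(Exception):
    """Base class for all package errors."""


class ValidationError(FabricMotionError):
    """Inputs violate a documented precondition or invariant."""


class ConfigError(ValidationError):
    """Configuration is inconsistent (e.g. sampling-rate mismatch)."""


class ParseError(FabricMotionError):
    """A file could not be parsed; message names the offending line."""


class MarkerNotFoundError(FabricMotionError):
    """No jump/tap synchronisation marker of sufficient amplitude found."""


class UndefinedCorrelationError(FabricMotionError):
    """Correlation requested on a zero-variance signal."""


class GravityEstimationError(FabricMotionError):
    """Gravity direction could not be estimated reliably."""
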