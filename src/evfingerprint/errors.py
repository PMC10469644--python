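"""Exception hierarchy shared across the package."""


class EVFingerprintError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EVFingerprintError):
    """A configuration value is invalid; the message names the offending field."""


class InputError(EVFingerprintError):
    """Input data violates a precondition (wrong patient mix, missing values, ...)."""


class FormatError(EVFingerprintError):
    """A file could not be parsed, or lacks a required channel or metadata keyword."""


class FoldError(EVFingerprintError):
    """Cross-validation folds cannot be constructed as requested."""


class SeparationError(EVFingerprintError):
    """Logistic maximum likelihood failed to converge (perfect separation)."""
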