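"""Exception hierarchy shared across the pipeline."""


class MinpopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MinpopError):
    """A configuration value is invalid or internally inconsistent."""


class ValidationError(MinpopError):
    """Inputs violate a precondition (mismatched samples, empty candidate sets...)."""


class DataError(MinpopError):
    """Malformed data content (e.g. allele index out of range)."""
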