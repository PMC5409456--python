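"""Package-wide exception types."""


class GlucodaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlucodaError):
    """A parameter set or config is incomplete or inconsistent."""


class ValidationError(GlucodaError):
    """Input data violate a documented contract."""


class NumericError(GlucodaError):
    """A numerical operation degenerated (NaN state, singular innovation)."""
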