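"""Exception types shared across the package."""


class DYLLDError(Exception):
    """Base class for package errors."""


class DataError(DYLLDError, ValueError):
    """Input data violates a contract (missing day, age out of table range...)."""


class ConfigurationError(DYLLDError, ValueError):
    """A configuration value is invalid or makes a quantity undefined."""


class ModelError(DYLLDError, RuntimeError):
    """Model estimation failed (e.g. no candidate threshold converged)."""
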