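"""Exception types shared across the package."""


class GcsImputeError(Exception):
    """Base class for package errors."""


class ConfigError(GcsImputeError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(GcsImputeError):
    """Input data violates a contract (ranges, required completeness)."""


class FitError(GcsImputeError):
    """A model fit failed after all stabilisation retries."""
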