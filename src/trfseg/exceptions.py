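"""Package-wide exception types."""


class TrfsegError(Exception):
    """Base class for all trfseg errors."""


class InvalidInputError(TrfsegError, ValueError):
    """Raised when an operation receives structurally invalid input."""


class UndefinedCorrelationError(TrfsegError, ValueError):
    """Raised when a Pearson correlation is requested for a zero-variance input."""


class UndefinedSNRError(TrfsegError, ValueError):
    """Raised when a signal-to-noise ratio is requested against a zero-power signal."""


class ConfigError(TrfsegError):
    """Raised for unparseable configuration files or unknown configuration keys."""
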