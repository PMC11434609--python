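"""Exception hierarchy shared across the pipeline."""


class NighthmmError(Exception):
    """Base class for all package errors."""


class FormatError(NighthmmError):
    """Malformed input file or inconsistent shapes between companion files."""


class ParameterError(NighthmmError):
    """Invalid numerical parameter (non-PD covariance, non-positive dwell, ...)."""


class ConfigurationError(NighthmmError):
    """Invalid configuration (empty state pool, unknown config key, ...)."""


class PreprocessingError(NighthmmError):
    """Data unsuitable for a preprocessing step (zero-variance channel, ...)."""
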