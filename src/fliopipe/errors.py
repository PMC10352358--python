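"""Exception types shared across the pipeline."""


class FlioError(Exception):
    """Base class for package-specific errors."""


class LowSignalError(FlioError):
    """Histogram total below the configured minimum photon count."""


class DegenerateInputError(FlioError):
    """Input carries no usable decay signal (empty or flat histogram)."""


class ConfigurationError(FlioError):
    """Invalid or incomplete configuration."""


class FormatError(FlioError):
    """A file does not conform to the expected on-disk layout."""
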