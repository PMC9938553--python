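"""Exception hierarchy shared across the pipeline."""


class CrcMethError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CrcMethError, ValueError):
    """Invalid configuration (thresholds, counts, probabilities)."""


class InputError(CrcMethError, ValueError):
    """Invalid or inconsistent input data."""


class PlateFormatError(InputError):
    """Structurally malformed qMSP plate data (with row provenance)."""
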