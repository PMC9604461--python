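"""Exception hierarchy shared across the pipeline stages."""


class DiaphosError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DiaphosError, ValueError):
    """A file or record violates the expected on-disk format."""


class DesignError(DiaphosError, ValueError):
    """Samples, stages or replicates are inconsistent with the design."""


class ConfigError(DiaphosError, ValueError):
    """A configuration value is invalid or out of range."""


class EmptyProfileError(DiaphosError, ValueError):
    """Every feature was removed by a filter, leaving nothing to analyse."""
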