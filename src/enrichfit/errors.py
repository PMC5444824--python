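"""Exception types shared across the package."""


class EnrichFitError(Exception):
    """Base class for all package-specific errors."""


class MissingIndexError(EnrichFitError, IOError):
    """A coordinate-sorted BAM/CRAM input lacks its index file."""


class ConfigurationError(EnrichFitError, ValueError):
    """Inconsistent inputs or an invalid filter configuration."""


class DegenerateDataError(EnrichFitError, ValueError):
    """Data carry no usable variation (e.g. all scores identical)."""
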