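"""Exception hierarchy shared across the package."""


class PromoRankError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PromoRankError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class InputFormatError(PromoRankError, ValueError):
    """A file violates its expected format (duplicate gene row, missing ID, ...)."""


class ManifestError(PromoRankError, ValueError):
    """The sample manifest disagrees with the expression matrices."""


class ValidationError(PromoRankError, ValueError):
    """Input data violates a precondition (empty universe, non-finite value, ...)."""


class ReferenceLookupError(PromoRankError, KeyError):
    """A name (contig, dataset id) is not present in the referenced object."""
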