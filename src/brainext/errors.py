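"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: ConfigurationError -> 2, data-shaped
errors (DimensionError, FormatError, DegenerateInputError) -> 3.
"""


class BrainExtError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(BrainExtError):
    """A config object or argument combination violates its invariants."""


class DimensionError(BrainExtError):
    """Array rank or shape incompatible with the requested operation."""


class FormatError(BrainExtError):
    """File is not readable as the expected on-disk format."""


class DegenerateInputError(BrainExtError):
    """Input is technically well-formed but carries no usable signal
    (e.g. a constant image offered for percentile normalization)."""


class StateError(BrainExtError):
    """Operation requested in an invalid object state (e.g. pseudo-label
    loss with entries whose snapshots were never frozen)."""
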