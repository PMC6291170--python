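"""Exception hierarchy used across the package."""


class AlternansError(Exception):
    """Base class for all package errors."""


class ConfigError(AlternansError):
    """Invalid configuration value (geometry sizes, fractions, protocol fields...)."""


class InvalidStateError(AlternansError):
    """An ionic state violates its invariants (gate outside [0, 1], non-finite V)."""


class InstabilityError(AlternansError):
    """A numerical update left the stable region; usually means dt is too large."""


class NumericalBlowupError(AlternansError):
    """Non-finite value produced during integration; names the offending variable/node."""


class InsufficientDataError(AlternansError):
    """Not enough points/beats for the requested measurement."""


class NotApplicableError(AlternansError):
    """The measurement does not apply to this input (e.g. block-site DI without block)."""


class FrameFormatError(AlternansError):
    """A persisted frame container or CSV table failed validation."""
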