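"""Exception hierarchy shared across the package."""


class InnerbarkError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(InnerbarkError):
    """Input file does not match the declared schema."""


class OrderingError(InnerbarkError):
    """Timestamps are not strictly increasing."""


class AlignmentError(InnerbarkError):
    """Two series expected on a common grid are not aligned."""


class EmptyInputError(InnerbarkError):
    """Operation received an empty series or table."""


class LengthError(InnerbarkError):
    """Series too short for the requested decomposition or fit."""


class DomainError(InnerbarkError):
    """Scalar argument outside its physical domain."""


class AnchorError(InnerbarkError):
    """The midnight anchor sample required by the exchange model is missing."""


class CollinearityError(InnerbarkError):
    """Design matrix is singular (e.g. xylem water potential constant)."""


class UndefinedCorrelationError(InnerbarkError):
    """Cross-correlation undefined because an input has zero variance."""


class PairingError(InnerbarkError):
    """Axial gradient requested for an unmatched upper/lower pair."""


class ConfigError(InnerbarkError):
    """Pipeline configuration is invalid."""
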