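"""Exception hierarchy shared across the package."""


class MedipChipError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedipChipError, ValueError):
    """Raised when an input violates a documented precondition."""


class CapacityError(MedipChipError):
    """Raised when a synthetic genome cannot hold the requested features."""


class PlacementError(MedipChipError):
    """Raised when a planted region falls outside the tiled probe space."""


class AlignmentError(MedipChipError):
    """Raised when two probe tracks do not share an identical probe set."""


class UnknownReferenceError(MedipChipError, KeyError):
    """Raised when an identifier is not present in the reference annotation."""
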