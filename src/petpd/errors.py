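"""Exception hierarchy shared across the analysis stages."""


class PetPdError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PetPdError, ValueError):
    """Raised when an input violates a documented precondition."""


class ComputationError(PetPdError, ArithmeticError):
    """Raised when a quantity cannot be computed from otherwise valid input
    (e.g. zero standard counts, all replicates excluded)."""


class ClassificationUnavailableError(PetPdError):
    """Raised when a growth curve cannot be classified (no measurement at or
    after the minimum follow-up day); never a silent default."""
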