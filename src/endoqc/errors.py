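"""Exception hierarchy shared by all endoqc modules."""


class EndoqcError(Exception):
    """Base class for all endoqc errors."""


class InvalidArgumentError(EndoqcError, ValueError):
    """An argument violates an operation's precondition."""


class ValidationError(EndoqcError, ValueError):
    """A record or config violates a domain invariant."""


class RoiNotFoundError(EndoqcError):
    """No bright region large enough to serve as the region of interest."""


class CalibrationError(EndoqcError):
    """The photocell calibration signal is unusable (non-positive)."""


class ConflictError(EndoqcError):
    """A store operation collides with an existing record."""


class NoBaselineError(EndoqcError):
    """No stored measurement exists to serve as the best-of-type baseline."""


class InsufficientDataError(EndoqcError):
    """Too few records for the requested longitudinal analysis."""
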