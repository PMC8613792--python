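"""Exception hierarchy shared across the package."""


class RapbeefError(Exception):
    """Base class for all package errors."""


class InputError(RapbeefError):
    """Malformed or missing user input (bad cell, missing operand, unit mismatch)."""


class DomainError(RapbeefError):
    """Mathematically invalid request (zero denominator, index outside [0, 100])."""


class DegenerateConfigurationError(RapbeefError):
    """Ordination cannot proceed (coincident reference points, identical rows)."""
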