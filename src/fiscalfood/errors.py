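"""Exception hierarchy.

All package errors derive from :class:`FiscalFoodError` so callers can catch
one base class; each subclass also derives from the matching builtin so that
generic handling (``except ValueError``) keeps working.
"""


class FiscalFoodError(Exception):
    """Base class for all fiscalfood errors."""


class ConfigurationError(FiscalFoodError, ValueError):
    """An input configuration violates an invariant; message names the field."""


class StructuralError(FiscalFoodError, ValueError):
    """Mismatched shapes, lengths or group sets between paired inputs."""


class DomainError(FiscalFoodError, ValueError):
    """A numeric argument is outside its mathematically valid domain."""


class MissingCoefficientError(FiscalFoodError, KeyError):
    """A lookup (food group, AME band, price variant, disease rate) failed."""
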