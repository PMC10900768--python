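"""Exception hierarchy for frosteis.

All package errors derive from :class:`FrosteisError` so callers can catch
one base class; the subclasses distinguish contract violations (bad input
data) from configuration and fixture problems.
"""


class FrosteisError(Exception):
    """Base class for all frosteis errors."""


class SpectrumFormatError(FrosteisError):
    """A spectrum file is missing required columns or is not parseable."""


class SpectrumValidationError(FrosteisError):
    """Spectrum content violates an invariant (non-finite, z_real <= 0, ...)."""


class InsufficientDataError(FrosteisError):
    """Too few points (spectrum rows or distinct temperatures) to proceed."""


class FixtureIntegrityError(FrosteisError):
    """The packaged reference table failed its integrity check."""


class ConfigurationError(FrosteisError):
    """A run or simulation configuration is inconsistent."""
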