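"""Exception hierarchy."""


class EptxError(Exception):
    """Base class for all package errors."""


class InputError(EptxError, ValueError):
    """Invalid user-supplied value (negative distance, malformed file, ...)."""


class ConfigurationError(EptxError, ValueError):
    """Inconsistent simulation configuration (e.g. unstable time step)."""


class NumericalError(EptxError, ArithmeticError):
    """A numerical routine failed to reach its tolerance."""


class FitError(EptxError, RuntimeError):
    """All optimization starts failed to converge."""
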