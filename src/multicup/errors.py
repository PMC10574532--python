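"""Exception hierarchy shared across the package."""


class MulticupError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MulticupError, ValueError):
    """An argument is outside the physically meaningful domain."""


class InsufficientDataError(MulticupError, ValueError):
    """Too few usable observations for the requested fit."""


class FitError(MulticupError, RuntimeError):
    """An optimiser failed to converge; carries the last iterate when known."""

    def __init__(self, message, last_iterate=None, best_rss=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.best_rss = best_rss


class IntegrationError(MulticupError, RuntimeError):
    """An ODE solve failed; carries the diagnostic state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


class ValidationError(MulticupError, ValueError):
    """A value object violates its invariants."""


class ParseError(MulticupError, ValueError):
    """A file could not be parsed; names the offending row when known."""
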