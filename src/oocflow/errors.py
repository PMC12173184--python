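"""Exception types shared across the package."""


class OocflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(OocflowError, ValueError):
    """A fluid or geometry object violates its physical invariants."""


class InsufficientDataError(OocflowError, ValueError):
    """Too few data points for the requested operation."""


class ConvergenceError(OocflowError, RuntimeError):
    """An iterative solve failed to reach the requested tolerance.

    Carries the residual history so the caller can inspect stagnation
    versus divergence.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])
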