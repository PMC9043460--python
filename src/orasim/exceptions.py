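"""Package-specific exception types."""


class GeometryError(ValueError):
    """Requested corneal geometry is infeasible (e.g. posterior ellipse undefined)."""


class ConvergenceError(RuntimeError):
    """An iterative solve failed to reach its tolerance.

    Attributes
    ----------
    residual : float
        Last relative residual reached before giving up.
    history : list of float
        Residual history, one entry per convergence check.
    """

    def __init__(self, message, residual=None, history=None):
        super().__init__(message)
        self.residual = residual
        self.history = list(history) if history is not None else []


class StabilityError(RuntimeError):
    """Explicit time integration blew up (NaN or runaway energy)."""


class ApplanationError(RuntimeError):
    """No applanation peak could be detected in a signal."""
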