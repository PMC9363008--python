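"""Exception types raised across the package."""


class ChemoengineError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ChemoengineError, ValueError):
    """A parameter value is outside its physically meaningful domain."""


class UnphysicalProfileError(ChemoengineError):
    """A steady profile took a non-positive value where the force law
    requires u > 0 (log-singular chemical potential)."""


class ConvergenceError(ChemoengineError):
    """An iterative solver failed to converge, or a discretized result did
    not pass its grid-refinement check."""


class StepError(ChemoengineError, RuntimeError):
    """A time step produced an invalid field state (e.g. negative
    concentration), usually a sign that dt is too large."""

    def __init__(self, message: str, step: int | None = None):
        self.step = step
        if step is not None:
            message = f"{message} (at step {step})"
        super().__init__(message)
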