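"""Exception hierarchy shared across the package."""


class PercspaceError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PercspaceError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(PercspaceError, ValueError):
    """A solver or pipeline configuration is inconsistent (e.g. an explicit
    scheme run above its stability bound)."""


class NumericalError(PercspaceError, RuntimeError):
    """The computation produced values outside its numerical contract."""


class DegenerateMetricError(PercspaceError, ValueError):
    """A perceived metric acquired a negative diagonal entry."""


class FitFailureError(PercspaceError, RuntimeError):
    """A least-squares fit could not produce a valid result."""


class CollapsedActivityError(PercspaceError, RuntimeError):
    """Total network activity fell to (or below) zero, so the normalised
    update of the attractor network is undefined."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"network activity collapsed at step {step}")


class PipelineError(PercspaceError, RuntimeError):
    """An end-to-end pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
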