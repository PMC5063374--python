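"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of a closed-form expression."""


class StabilityError(ValueError):
    """A linear model is unstable at the requested coupling (spectral radius >= 1)."""


class DivergenceError(RuntimeError):
    """A numerical integration produced non-finite state."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class MultiBranchError(ValueError):
    """A fitted polynomial has no dominant monotone branch over its fit domain."""

    def __init__(self, message: str, turning_points=()):
        super().__init__(message)
        self.turning_points = tuple(turning_points)
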