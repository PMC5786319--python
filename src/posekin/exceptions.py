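"""Exception types raised across the package."""


class ValidationError(ValueError):
    """An input violates a documented invariant; the message names it."""


class NotConvergedError(RuntimeError):
    """An iterative estimator ran out of iterations; carries diagnostics."""

    def __init__(self, message: str, n_iterations: int | None = None,
                 last_change: float | None = None):
        super().__init__(message)
        self.n_iterations = n_iterations
        self.last_change = last_change


class UnreachableStateError(ValueError):
    """A target state set cannot be reached from the source set."""
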