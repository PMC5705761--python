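"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


class NumericalBlowupError(RuntimeError):
    """Raised when an integration step produces non-finite coordinates.

    Carries the indices of the offending trajectories in ``trajectory_indices``.
    """

    def __init__(self, message: str, trajectory_indices=None):
        super().__init__(message)
        self.trajectory_indices = tuple(trajectory_indices or ())
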