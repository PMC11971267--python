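"""Exception hierarchy for skillnet."""


class SkillnetError(Exception):
    """Base class for all package errors."""


class ValidationError(SkillnetError, ValueError):
    """Invalid argument or malformed input object."""


class DegenerateInputError(SkillnetError, ValueError):
    """Input is structurally degenerate (constant column, singular matrix, ...)."""


class ConstructionError(SkillnetError, RuntimeError):
    """A synthetic precision matrix could not be made positive definite."""


class ConvergenceError(SkillnetError, RuntimeError):
    """An iterative solver failed to converge.

    Carries the penalty value and iteration count for diagnosis.
    """

    def __init__(self, message: str, lam: float | None = None, n_iter: int | None = None):
        super().__init__(message)
        self.lam = lam
        self.n_iter = n_iter


class BootstrapError(SkillnetError, RuntimeError):
    """Too many bootstrap replicates failed estimation."""
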