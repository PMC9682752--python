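"""Exception hierarchy.

Two families matter for the CLI exit-code contract: input/validation problems
(exit code 2) and numerical failures (exit code 3).
"""


class ApyCoreError(Exception):
    """Base class for all package errors."""


class ValidationError(ApyCoreError):
    """Invalid input: bad genotype codes, shape mismatches, infeasible configs."""

    exit_code = 2


class InvalidGenotypeError(ValidationError):
    """A genotype entry outside {0, 1, 2} (or missing) was encountered."""


class DegenerateDataError(ValidationError):
    """Data carries no usable variation (e.g. all markers monomorphic, v = 0)."""


class NumericalError(ApyCoreError):
    """Numerical failure: singular factorisations, non-convergence, rank exhaustion."""

    exit_code = 3


class FactorizationError(NumericalError):
    """A symmetric positive-definite factorisation failed."""


class RankExhaustedError(NumericalError):
    """Greedy core selection ran out of linearly independent animals.

    Attributes
    ----------
    n_selected : number of animals that were selectable before exhaustion.
    """

    def __init__(self, msg: str, n_selected: int):
        super().__init__(msg)
        self.n_selected = n_selected


class ConvergenceError(NumericalError):
    """Iterative solver failed to reach tolerance; carries the iteration trace."""

    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = list(residuals) if residuals is not None else []


class UndefinedStatisticError(ValidationError):
    """A validation statistic is undefined (e.g. zero-variance GEBV)."""
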