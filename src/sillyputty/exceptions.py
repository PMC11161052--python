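"""Named errors raised across the package."""


class SillyPuttyError(Exception):
    """Base class for all package errors."""


class MissingValuesError(SillyPuttyError):
    """A matrix contains NaN or infinite entries."""


class InvalidMatrixError(SillyPuttyError):
    """A matrix violates a structural invariant (shape, ids, values)."""


class AsymmetricDistanceError(InvalidMatrixError):
    """A distance matrix is asymmetric beyond tolerance."""


class NegativeDistanceError(InvalidMatrixError):
    """A distance matrix contains negative entries."""


class ZeroVarianceError(SillyPuttyError):
    """A sample row has zero variance, so a correlation is undefined."""


class LabelMismatchError(SillyPuttyError):
    """Label vector does not align with the matrix it is paired with."""


class DegenerateClusteringError(SillyPuttyError):
    """An operation would leave (or has reached) fewer than two clusters.

    Carries the iteration ``trace`` accumulated so far when raised from the
    refinement loop.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class SimulationError(SillyPuttyError):
    """A simulation configuration is infeasible."""
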