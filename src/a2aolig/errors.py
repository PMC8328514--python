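"""Exception hierarchy shared across the analysis stages."""


class A2aoligError(Exception):
    """Base class for all package errors."""


class ValidationError(A2aoligError):
    """An input violates a documented invariant (non-monotonic axis,
    overlapping windows, non-electroneutral species, schema mismatch...)."""


class ParseError(A2aoligError):
    """A file could not be parsed; the message names the offending line."""


class DegenerateInputError(A2aoligError):
    """The input is formally valid but carries no usable signal
    (constant trace, all-zero lane profile)."""


class FitFailureError(A2aoligError):
    """Nonlinear fit did not converge within the bounded restart policy."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class UndefinedRatioError(A2aoligError):
    """A monomer-equivalent ratio was requested with zero/absent monomer area."""


class UnsupportedInputError(A2aoligError):
    """The operation needs a richer representation than the input carries
    (e.g. hydrogen-bond geometry on coarse sites without hydrogens)."""


class GenerationError(A2aoligError):
    """A synthetic-data plan is infeasible as specified."""
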