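"""Exception hierarchy for aspuw."""


class AspuwError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AspuwError, ValueError):
    """An input file or in-memory object violates a documented invariant."""


class AlignmentError(ValidationError):
    """Sample identifiers cannot be matched across input tables."""


class FitError(AspuwError, RuntimeError):
    """The null mixed-model fit failed to converge.

    Carries the optimisation trace (list of (params, objective) tuples)
    in the ``trace`` attribute when available.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ComputationError(AspuwError, RuntimeError):
    """A downstream computation received degenerate input (e.g. all SNPs
    monomorphic, or a zero-variance CpG reaching the weight step)."""
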