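"""Exception and warning hierarchy."""


class CornasError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CornasError, ValueError):
    """A parameter is outside its mathematical domain."""


class CoverageError(ParameterError):
    """Sequencing coverage is outside (0, 1).

    Coverage above one means more fragments were sequenced than the
    estimated fragment population contains; the method is not
    recommended in that regime.
    """


class CountTableError(CornasError, ValueError):
    """A gene-count table failed validation or parsing."""


class TruncationError(CornasError, RuntimeError):
    """The brute-force posterior sum could not reach the requested
    tail-mass tolerance within the iteration cap."""

    def __init__(self, message: str, achieved_bound: float):
        super().__init__(message)
        self.achieved_bound = achieved_bound


class GPValidityWarning(UserWarning):
    """The Generalized Poisson parameterisation left its validity region
    (mean-variance ratio m >= 4, i.e. coverage >= 0.75)."""


class RocMonotonicityWarning(UserWarning):
    """An ROC curve's TPR decreased with increasing FPR after sorting."""
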