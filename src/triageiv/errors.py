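"""Exception taxonomy shared across the estimation modules."""


class TriageIVError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TriageIVError):
    """A simulation or analysis configuration violates its invariants."""


class CohortError(TriageIVError):
    """A cohort table fails structural validation (missing column, non-binary
    treatment/outcome, duplicate ids ...)."""


class RankDeficientDesignError(TriageIVError):
    """Design matrix is not of full column rank.

    ``columns`` names the offending (collinear) regressors when they can be
    identified.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


class ConvergenceError(TriageIVError):
    """An iterative maximum-likelihood fit failed to converge."""


class SeparationError(ConvergenceError):
    """Complete or quasi-complete separation detected in a binary-response fit."""


class DegenerateResponseError(TriageIVError):
    """A binary response takes a single value, so the model is not estimable."""


class UninformativeInstrumentError(TriageIVError):
    """The instrument induces no variation in treatment (zero Wald denominator
    or a constant first-stage prediction)."""


class BootstrapFailureError(TriageIVError):
    """Too many bootstrap replicates failed for the interval to be trusted."""
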