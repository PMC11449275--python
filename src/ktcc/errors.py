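"""Exception hierarchy shared across the package."""


class KtccError(Exception):
    """Base class for all package-specific errors."""


class InvalidInstanceError(KtccError):
    """An instance violates a structural invariant (empty, non-integer, non-positive)."""


class SizeLimitError(KtccError):
    """A problem size exceeds a guard against exponential blowup."""


class InfeasibleBandError(KtccError):
    """Rejection sampling failed: the requested constrainedness band is too
    narrow for integer rounding at this item count."""


class BracketError(KtccError):
    """The satisfiability-probability bracket does not straddle 0.5."""


class ConfigurationError(KtccError):
    """Inconsistent user configuration (overlapping bands, indivisible counts...)."""


class QuotaTimeoutError(KtccError):
    """A stimulus design cell could not be filled within the attempt budget."""


class LabelValidationError(KtccError):
    """A stored satisfiability label disagrees with the exact solver's verdict."""


class CollinearityError(KtccError):
    """A design matrix is rank deficient after adding nuisance columns."""

    def __init__(self, message, dependent_columns=()):
        super().__init__(message)
        self.dependent_columns = list(dependent_columns)


class SeparationError(KtccError):
    """Logistic-regression outcomes are perfectly separable; the MLE diverges."""


class FitConvergenceError(KtccError):
    """Iterative maximum-likelihood fitting failed to converge."""


class SampleSizeError(KtccError):
    """Too few participants (or observations) for the requested test."""
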