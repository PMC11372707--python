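"""Exception hierarchy for forcefluct.

All argument-validation failures derive from :class:`InvalidArgumentError`
(itself a ``ValueError``) so callers can catch one base class.
"""


class ForceFluctError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ForceFluctError, ValueError):
    """An argument violated a documented precondition."""


class EmptySeriesError(InvalidArgumentError):
    """No samples remain after an exclusion step."""


class ZeroVarianceError(InvalidArgumentError):
    """A constant series was passed where variance is required."""


class UndefinedCVError(InvalidArgumentError):
    """Coefficient of variation is undefined (zero-mean series)."""


class DegenerateFluctuationError(InvalidArgumentError):
    """A fluctuation value of exactly zero makes the log-log fit impossible."""


class UndefinedEntropyError(ForceFluctError):
    """No template matches at length m+1; entropy is reported missing."""


class RankDeficiencyError(InvalidArgumentError):
    """The fixed-effects design matrix is singular."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"design is rank deficient; aliased terms: {self.aliased}")


class ConvergenceError(ForceFluctError):
    """The mixed-model optimizer failed to converge."""


class NestingViolationError(InvalidArgumentError):
    """A 'full' model fit worse than its nested reduction beyond tolerance."""
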