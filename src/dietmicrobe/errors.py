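"""Exception types shared across the pipeline stages."""


class DietMicrobeError(Exception):
    """Base class for all package errors."""


class InvalidTruthError(DietMicrobeError, ValueError):
    """A synthetic ground-truth object violates its invariants."""


class InvalidConfigError(DietMicrobeError, ValueError):
    """A configuration value is out of range or inconsistent."""


class ConvergenceError(DietMicrobeError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class DegenerateDistributionError(DietMicrobeError, ValueError):
    """A distribution is too degenerate to cut into categories."""


class PartitionError(DietMicrobeError, ValueError):
    """The increased/decreased genus partition is unusable (one side empty)."""


class UndefinedOrError(DietMicrobeError, ValueError):
    """An odds ratio is undefined for the given contingency cells."""


class SeparationError(DietMicrobeError, RuntimeError):
    """Perfect separation in a logistic fit; the offending covariate is named."""
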