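"""Exception hierarchy shared across the package."""


class TriageSimError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TriageSimError):
    """A cohort specification violates its invariants (e.g. all-zero marginals)."""


class UnattainablePrevalenceError(TriageSimError):
    """Intercept calibration could not bracket the requested prevalence."""


class UndefinedProbabilityError(TriageSimError):
    """True outcome probability requested for a record with missing vitals."""


class CategorizationError(TriageSimError):
    """A value falls outside every category of its predictor."""


class UnfittableError(TriageSimError):
    """A learner cannot be fitted (e.g. single-class outcome)."""


class UndefinedRateError(TriageSimError):
    """A rate has a zero denominator or a single-class input."""


class UndefinedSlopeError(TriageSimError):
    """Calibration slope undefined (zero variance of the linear predictor)."""


class SchemaError(TriageSimError):
    """Input columns do not match what a fitted model expects."""


class SizingError(TriageSimError):
    """Cohort too small for the requested disjoint train/validation/test draw."""


class ConfigError(TriageSimError):
    """Malformed or out-of-range configuration file."""
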