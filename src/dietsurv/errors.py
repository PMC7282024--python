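"""Exception hierarchy.

The CLI maps these onto distinct exit codes (configuration, data,
convergence) so shell pipelines can branch on failure class.
"""


class DietSurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DietSurvError):
    """A config object/file is invalid (bad field, unknown rule, missing path)."""


class DataError(DietSurvError):
    """Input data violate a contract (missing column, out-of-range value)."""


class MappingError(DataError):
    """A compound or component cannot be resolved against its lookup table."""


class CohortStatisticError(DataError):
    """A cohort-relative statistic (median, quintile) is undefined at this n."""


class DegeneracyError(DataError):
    """A computation is degenerate (constant regressor, <5 distinct values)."""


class FitError(DietSurvError):
    """A survival model cannot be fit (no events, empty design)."""


class ConvergenceError(FitError):
    """The partial-likelihood optimiser failed to converge."""
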