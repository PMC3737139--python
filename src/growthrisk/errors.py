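"""Exception hierarchy.

Every error raised intentionally by the package derives from
:class:`GrowthRiskError`, so callers (and the CLI) can separate data problems
from programming bugs.
"""


class GrowthRiskError(Exception):
    """Base class for all growthrisk errors."""


class DomainError(GrowthRiskError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class AgeRangeError(GrowthRiskError, ValueError):
    """An age falls outside the span covered by a reference or equation set."""


class ReferenceTableError(GrowthRiskError, ValueError):
    """An LMS reference table is malformed or incomplete."""


class UnitError(GrowthRiskError, ValueError):
    """A measurement carries an unknown or unparsable unit."""


class DegenerateModelError(GrowthRiskError, ValueError):
    """A fit is degenerate (zero residual variance, constant predictor...)."""


class SeparationError(GrowthRiskError):
    """Complete or quasi-complete separation detected in a logistic fit."""


class ConvergenceError(GrowthRiskError):
    """Iterative maximum-likelihood fitting failed to converge."""


class CohortFormatError(GrowthRiskError, ValueError):
    """A cohort table has an unknown column or an unparsable row value."""


class ConfigError(GrowthRiskError, ValueError):
    """A model-configuration file violates the expected schema."""
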