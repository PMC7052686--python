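"""Exception hierarchy for the screening tool.

All errors derive from :class:`BVNLError` (itself a ``ValueError``) so callers
can catch everything the package raises with one except clause.
"""


class BVNLError(ValueError):
    """Base class for all bvnlscreen errors."""


class InsufficientDataError(BVNLError):
    """Fewer observations than the operation requires."""


class DegenerateCohortError(BVNLError):
    """A log-analyte column has zero variance; no model can be fitted."""


class InvalidValueError(BVNLError):
    """A raw analyte value is nonpositive after detection-limit flooring."""


class SingularCorrelationError(BVNLError):
    """|rho| >= 1: the bivariate normal is singular."""


class InvalidProbabilityError(BVNLError):
    """A probability argument falls outside (0, 1)."""


class UndefinedPPVError(BVNLError):
    """PPV denominator Sens*Prev + FP*(1-Prev) is zero."""


class ConfigurationError(BVNLError):
    """A generator/simulation/report configuration is invalid or incomplete."""


class CohortValidationError(BVNLError):
    """A cohort table violates the required schema."""
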