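"""Exception hierarchy used across the package.

Every error raised on purpose derives from :class:`CombatCVError`, so callers
can catch the package's failures without masking programming errors.
"""


class CombatCVError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CombatCVError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(CombatCVError, ValueError):
    """A table is missing required columns, has duplicate IDs, or holds
    labels outside the expected vocabulary."""


class GenerationError(CombatCVError, RuntimeError):
    """Synthetic-data generation could not produce a valid object
    (e.g. a perturbed correlation matrix that cannot be repaired)."""


class UndefinedCorrelationError(CombatCVError, ValueError):
    """Pearson correlation is undefined (zero-variance series); the message
    names the ROI."""


class EmptyFeatureError(CombatCVError, ValueError):
    """A pruning or selection step removed every feature/ROI."""


class FitError(CombatCVError, RuntimeError):
    """Harmonization or classifier fitting failed; the message names the
    site or the cause."""


class DegenerateFeatureError(FitError):
    """A feature has zero residual variance in the reference set."""


class UnknownSiteError(CombatCVError, KeyError):
    """A subject's site was not seen when the harmonization model was fit.

    Raised instead of silently passing data through: inside a CV loop this
    signals a broken fold plan.
    """


class UndefinedMetricError(CombatCVError, ValueError):
    """A metric (AUC) is undefined because only one class is present."""


class EvaluationError(CombatCVError, RuntimeError):
    """An evaluation protocol cannot run (e.g. no qualifying site pairs)."""


class AggregationError(CombatCVError, ValueError):
    """Importance aggregation received inconsistent or incomplete folds."""
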