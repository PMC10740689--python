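"""Exception hierarchy for the pipeline.

Every error raised on a user-facing path derives from :class:`PfssError`
so CLI entry points can catch one type and exit with a named error class.
"""


class PfssError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PfssError):
    """A table file does not have the expected shape (missing column,
    unparseable cell)."""


class ValidationError(PfssError):
    """A parsed record violates a table invariant."""


class DuplicateKeyError(ValidationError):
    """Two rows share a key that must be unique within one table."""


class DomainValueError(PfssError, ValueError):
    """A numeric argument is outside its mathematical domain
    (probability outside [0, 1], non-finite Z, m < 1, ...)."""


class CalibrationError(PfssError):
    """A calibration entry is unusable (non-positive standard deviation)."""


class UnknownModelError(PfssError, KeyError):
    """A site references a SeqFEATURE model with no calibration entry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class NormalizationError(PfssError):
    """The gamma normalization factor is non-positive or missing."""


class AssessmentError(PfssError):
    """Aggregation was requested over an empty collection."""


class StatsError(PfssError):
    """Base class for benchmark-statistics errors."""


class CorrelationError(StatsError):
    """Correlation undefined (fewer than 3 points or zero variance)."""


class LeverageError(StatsError):
    """Leverages undefined (degenerate predictor)."""


class ComparisonError(StatsError):
    """A pairwise comparison received an empty sample."""


class RankingError(StatsError):
    """An unknown ranking key or an invalid top-k request."""


class SimulationSpecError(PfssError):
    """A synthetic-campaign specification field is invalid."""
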