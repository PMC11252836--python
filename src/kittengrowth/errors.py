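"""Exception hierarchy for cohort validation and model fitting."""


class KittenGrowthError(Exception):
    """Base class for package errors."""


class SchemaError(KittenGrowthError):
    """The cohort file is missing a required column or is otherwise malformed."""


class RowValidationError(KittenGrowthError):
    """A single cohort row violates a record invariant.

    Carries the row number (1-based, excluding header) and the offending field.
    """

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        super().__init__(message)
        self.row = row
        self.field = field


class BreedLookupError(KittenGrowthError):
    """A breed has no entry in the breed threshold table."""


class ConfigError(KittenGrowthError):
    """Invalid analysis or simulation configuration."""


class InsufficientDataError(KittenGrowthError):
    """Too few observations for the requested statistic."""


class RankDeficiencyError(KittenGrowthError):
    """A factorial cell is empty so the interaction design is rank deficient."""


class SeparationError(KittenGrowthError):
    """A fitted cell has empirical mortality 0 or 1; marginal means are undefined."""


class NoSplitError(KittenGrowthError):
    """Cross-validated threshold search failed in more than half the folds."""
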