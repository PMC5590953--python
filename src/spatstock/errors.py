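"""Exception hierarchy.

All package errors derive from :class:`SpatstockError` so callers can catch
one base class at CLI level.
"""


class SpatstockError(Exception):
    """Base class for all spatstock errors."""


class DegenerateDomainError(SpatstockError):
    """Too few / collinear points: no two-dimensional domain can be meshed."""


class SingularElementError(SpatstockError):
    """A mesh triangle has (numerically) zero area."""


class OutOfDomainError(SpatstockError):
    """Requested locations fall outside the triangulated domain."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class StationarityError(SpatstockError):
    """AR(1) persistence coefficient outside (-1, 1)."""


class ConditioningError(SpatstockError):
    """A precision matrix could not be factorized (not positive definite)."""


class ConvergenceError(SpatstockError):
    """Inner Newton or outer optimizer failed to converge."""


class SchemaError(SpatstockError):
    """Tabular input does not match the documented schema."""


class MissingDataError(SpatstockError):
    """Required covariate or field values are missing (no silent imputation)."""


class ConfigError(SpatstockError):
    """Invalid run configuration."""


class ComparabilityError(SpatstockError):
    """Model-comparison inputs were not fit on identical data."""
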