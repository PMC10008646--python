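"""Exception hierarchy for cytoflmm.

All package errors derive from :class:`CytoflmmError` so callers can catch
one base class; most also derive from the closest builtin (ValueError etc.).
"""


class CytoflmmError(Exception):
    """Base class for all cytoflmm errors."""


class SchemaError(CytoflmmError, ValueError):
    """An input table is missing required columns or has the wrong layout."""


class IntegrityError(CytoflmmError, ValueError):
    """Duplicate or contradictory rows in an input table."""


class ConfigError(CytoflmmError, ValueError):
    """An invalid configuration value (wavelet name, level, FDR level, ...)."""


class DomainError(CytoflmmError, ValueError):
    """A numeric argument outside its mathematical domain."""


class ShapeError(CytoflmmError, ValueError):
    """Mismatched array shapes or ragged panels."""


class CoverageError(CytoflmmError, ValueError):
    """A required design cell (e.g. a concentration level) has no data."""


class ExtrapolationError(CytoflmmError, ValueError):
    """A target grid extends beyond the observed time range."""


class IdentifiabilityError(CytoflmmError, ValueError):
    """Variance components cannot be separated from the available replication."""


class RankDeficiencyError(CytoflmmError, ValueError):
    """A scatter/design matrix is singular."""


class ConvergenceError(CytoflmmError, RuntimeError):
    """An iterative fit did not converge; carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class StageError(CytoflmmError, RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""
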