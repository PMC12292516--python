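"""Exception hierarchy.

All somascan errors derive from :class:`SomascanError` so callers can catch
the package's failures with a single except clause; subclasses distinguish
domain violations (bad measurement values) from interface problems (bad
tables, bad arguments, degenerate fits).
"""


class SomascanError(Exception):
    """Base class for all somascan errors."""


class DomainError(SomascanError, ValueError):
    """A measurement or derived quantity is outside its mathematical domain.

    The message names the offending field so cohort-level runs can report
    which input broke (e.g. a male record with waist <= neck, whose log
    argument would be non-positive).
    """


class ArgumentError(SomascanError, ValueError):
    """A structurally invalid argument (empty pair list, missing hips, ...)."""


class SingularFitError(SomascanError, ValueError):
    """A regression cannot be fit (degenerate predictor variance)."""


class UndefinedStatisticError(SomascanError, ValueError):
    """A statistic is undefined for the data (e.g. ICC with zero
    between-subject variance)."""


class SchemaError(SomascanError, ValueError):
    """A table is missing required columns or has wrong dimensions."""


class ConfigError(SomascanError, ValueError):
    """An infeasible simulation or I/O configuration."""
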