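"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`RadAncestryError`, so callers can catch one type at pipeline level.
"""


class RadAncestryError(Exception):
    """Base class for all package errors."""


class IdentifierError(RadAncestryError, KeyError):
    """Unknown sample, population, or individual identifier."""


class CoordinateError(RadAncestryError, ValueError):
    """Chromosome/interval not addressable on the given grid or table."""


class InsufficientDataError(RadAncestryError, ValueError):
    """Too few samples/sites/windows for the requested statistic."""


class DivergenceError(InsufficientDataError):
    """Populations not diverged enough for ancestry assignment (p_nat <= p_src)."""


class DegenerateTableError(RadAncestryError, ValueError):
    """2x2 contingency table with a zero row or column margin."""


class DomainError(RadAncestryError, ValueError):
    """Numeric argument outside its mathematical domain."""


class ConfigError(RadAncestryError, ValueError):
    """Invalid simulation or model configuration."""


class GridMismatchError(RadAncestryError, ValueError):
    """Objects built on different window grids were combined."""
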