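"""Exception hierarchy shared across the package."""


class PondpopError(Exception):
    """Base class for all pondpop errors."""


class SchemaError(PondpopError, ValueError):
    """An input table is missing a mandatory column or is otherwise malformed."""


class TableParseError(PondpopError, ValueError):
    """A cell could not be parsed; carries the offending row where possible."""


class ValidationError(PondpopError, ValueError):
    """A constructed object violates a domain invariant."""


class AlignmentError(PondpopError, ValueError):
    """Sequences that must share an alignment length do not."""


class StatisticError(PondpopError, ValueError):
    """A statistic is undefined for the given input (e.g. n < 2)."""


class ConfigError(PondpopError, ValueError):
    """A pipeline configuration is contradictory or incomplete."""
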