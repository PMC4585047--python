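"""Exception hierarchy for fosnet.

All package errors derive from :class:`FosnetError` so callers can catch a
single base class; each subclass also inherits the matching builtin
(``ValueError`` / ``RuntimeError``) for idiomatic handling.
"""


class FosnetError(Exception):
    """Base class for all fosnet errors."""


class SpecificationError(FosnetError, ValueError):
    """An invalid generator or network specification (e.g. hub index out of range)."""


class GenerationError(FosnetError, RuntimeError):
    """Synthetic-data generation failed (e.g. correlation matrix not repairable to PSD)."""


class ParseError(FosnetError, ValueError):
    """A sample-table file or config failed validation; message names the offending field."""


class DesignError(FosnetError, ValueError):
    """The factorial design is unusable (empty or under-filled treatment × phase cell)."""


class DegenerateDataError(FosnetError, ValueError):
    """Data carry no usable variation (zero residual variance, constant region column)."""


class InsufficientDataError(FosnetError, ValueError):
    """Too few observations for the requested statistic; message names the region pair/group."""
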