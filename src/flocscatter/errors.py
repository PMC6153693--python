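"""Exception hierarchy for flocscatter.

All errors raised by the library derive from :class:`FlocScatterError` so
callers (and the CLI) can catch library failures with a single ``except``.
"""


class FlocScatterError(Exception):
    """Base class for all flocscatter errors."""


class DomainError(FlocScatterError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class GridSpanError(FlocScatterError, ValueError):
    """A q-grid does not span the region an operation needs."""


class InsufficientDataError(FlocScatterError, ValueError):
    """Too few data points to carry out a fit or interval estimate."""


class NoRegimeError(FlocScatterError, RuntimeError):
    """No power-law regime could be located on a scattering curve."""


class DegenerateDistributionError(FlocScatterError, ValueError):
    """A size distribution has no usable mass (all-zero weights)."""


class SchemaError(FlocScatterError, ValueError):
    """An input file does not match the declared CSV/config schema."""
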