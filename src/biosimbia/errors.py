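"""Exception hierarchy for the budget-impact pipeline.

Every stage rejects invalid input with a located error rather than
silently coercing; downstream code can catch :class:`BiaError` to map
failures to a nonzero exit status.
"""


class BiaError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(BiaError):
    """An input table is missing a required column or has the wrong layout."""


class InputValidationError(BiaError):
    """A row violates a typed invariant (negative volume, bad date, ...)."""

    def __init__(self, message: str, *, table: str | None = None, row: int | None = None):
        loc = ""
        if table is not None:
            loc = f" [table={table}" + (f", row={row}]" if row is not None else "]")
        super().__init__(message + loc)
        self.table = table
        self.row = row


class ReferentialError(BiaError):
    """A row references a molecule code that does not resolve."""


class UnpriceableError(BiaError):
    """A product class has consumption in a month with no resolvable price."""


class DiscountEstimationError(BiaError):
    """A hospital molecule has neither tender data nor discount observations."""


class ConfigError(BiaError):
    """An engine / sensitivity configuration is internally inconsistent."""
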