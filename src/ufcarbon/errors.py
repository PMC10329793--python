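"""Exception types shared across the package."""


class UFCarbonError(Exception):
    """Base class for all package errors."""


class TableParseError(UFCarbonError):
    """A fixture or user table could not be parsed.

    Carries the offending row and column where known so that malformed
    inventory inputs can be fixed without guesswork.
    """

    def __init__(self, message, *, row=None, column=None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class ValidationError(UFCarbonError):
    """A domain value violates an invariant (negative stock, bad fraction...)."""


class ConfigurationError(UFCarbonError):
    """Pipeline configuration is incomplete (e.g. an RU has no density rule)."""


class NoDataError(UFCarbonError):
    """An estimator has no usable observations (all points discarded, ...)."""
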