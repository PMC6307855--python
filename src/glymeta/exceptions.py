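"""Exception hierarchy shared across the package."""


class GlymetaError(Exception):
    """Base class for all package errors."""


class ValidationError(GlymetaError):
    """A study record or input table violates the schema invariants."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None:
            loc += f" [row {row}"
            loc += f", column '{column}']" if column is not None else "]"
        elif column is not None:
            loc += f" [column '{column}']"
        super().__init__(message + loc)


class DegenerateInputError(GlymetaError):
    """Inputs are formally valid but make the requested statistic undefined."""


class ConvergenceError(GlymetaError):
    """Iterative variance estimation failed to converge.

    Carries ``last_iterate``, the value of tau-squared at the final iteration,
    so callers can inspect how far the algorithm got.
    """

    def __init__(self, message: str, last_iterate: float):
        self.last_iterate = last_iterate
        super().__init__(f"{message} (last iterate tau2={last_iterate:.6g})")


class ConstantModeratorError(GlymetaError):
    """A moderator takes a single value across all usable records."""


class ConfigError(GlymetaError):
    """An analysis or simulation configuration document is invalid."""
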