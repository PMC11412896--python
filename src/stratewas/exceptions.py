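"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`StratewasError`
so pipeline drivers can distinguish bad inputs from genuine bugs.
"""


class StratewasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StratewasError, ValueError):
    """Invalid configuration object or incompatible option combination."""


class InsufficientDataError(StratewasError, ValueError):
    """Too few samples/estimates to fit the requested model."""


class RankDeficientError(StratewasError, ValueError):
    """Design matrix is rank deficient.

    Carries the names of the offending (collinear) columns.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class InputError(StratewasError, ValueError):
    """Malformed numeric input (non-finite statistics, out-of-range values)."""


class ParseError(StratewasError, ValueError):
    """Malformed on-disk table; message names the file and line."""


class SchemaError(StratewasError, ValueError):
    """A table is missing mandatory columns."""


class SeparationError(StratewasError, ValueError):
    """Perfect separation in a logistic fit: no finite MLE exists."""


class DegenerateInputError(StratewasError, ValueError):
    """Structurally valid input on which the operation is undefined."""
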