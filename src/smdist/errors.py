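"""Exception hierarchy shared across the package.

Everything raised on user input derives from :class:`SmdistError`, so callers
(and the CLI) can catch one base class and still get specific types in tests.
"""


class SmdistError(Exception):
    """Base class for all package-specific errors."""


class InvalidWordError(SmdistError):
    """A word label is empty (after trimming) or otherwise unusable."""


class SchemaError(SmdistError):
    """An input file is missing a required column."""


class ValidationError(SmdistError):
    """A cell failed validation (non-numeric or out-of-bounds rating)."""


class DuplicateWordError(SmdistError):
    """Two rows map to the same normalised word key."""


class DuplicatePairError(SmdistError):
    """A benchmark contains the same unordered word pair twice."""


class WordNotFoundError(SmdistError, KeyError):
    """A requested word is not present in the norms table."""

    def __init__(self, key: str):
        super().__init__(key)
        self.key = key

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return f"word not found in norms table: {self.key!r}"


class UndefinedDirectionError(SmdistError):
    """Cosine distance requested for an all-zero vector (no direction)."""


class UndefinedCorrelationError(SmdistError):
    """Correlation requested where one variable is constant."""


class MetricSpecError(SmdistError):
    """A metric specification is invalid (e.g. mahalanobis without covariance)."""


class InsufficientDataError(SmdistError):
    """Not enough rows/points for the requested computation."""


class ParseError(SmdistError):
    """A benchmark or predictor file row could not be parsed."""
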