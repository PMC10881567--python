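"""Exception hierarchy.

Every error raised by the package derives from :class:`FuzzydxError`, so
callers (notably the CLI) can catch one type and exit cleanly.
"""


class FuzzydxError(Exception):
    """Base class for all package errors."""


# --- fuzzy engine -----------------------------------------------------------

class NonFiniteInput(FuzzydxError):
    """Crisp input was NaN or infinite; the feature must be treated as missing."""


class EmptyOutput(FuzzydxError):
    """No rule fired: the aggregated output fuzzy set has zero mass."""


# --- rulebase ---------------------------------------------------------------

class ParseError(FuzzydxError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UnknownVariable(FuzzydxError):
    pass


class UnknownLabel(FuzzydxError):
    pass


# --- taxonomy ---------------------------------------------------------------

class TaxonomyError(FuzzydxError):
    pass


class CycleDetected(TaxonomyError):
    pass


class OrphanConcept(TaxonomyError):
    pass


class DuplicateId(TaxonomyError):
    pass


class CrossCategoryComparison(TaxonomyError):
    pass


class EmptyTerm(FuzzydxError):
    pass


# --- patient model ----------------------------------------------------------

class MissingIdColumn(FuzzydxError):
    pass


class NonNumericValue(FuzzydxError):
    def __init__(self, message: str, row: int, column: str):
        super().__init__(f"{message} (row {row}, column {column!r})")
        self.row = row
        self.column = column


class UnknownPatientId(FuzzydxError):
    pass


# --- synthetic cohorts ------------------------------------------------------

class InvalidSpec(FuzzydxError):
    pass
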