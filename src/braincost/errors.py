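"""Exception hierarchy.

Errors are split so a command-line caller can distinguish bad inputs
(schema/validation/vocabulary/coverage) from internal computation problems.
"""


class BraincostError(Exception):
    """Base class for all package errors."""


class SchemaError(BraincostError):
    """An input table is missing mandatory columns or cannot be parsed."""


class CorpusValidationError(BraincostError):
    """One or more corpus rows violate the record invariants.

    ``errors`` holds ``(row_number, message)`` pairs; row numbers are
    1-based positions in the data section of the file.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = list(errors)
        detail = "; ".join(f"row {n}: {msg}" for n, msg in self.errors)
        super().__init__(f"{len(self.errors)} invalid corpus row(s): {detail}")


class VocabularyError(BraincostError):
    """A disorder id is not part of the 19-disorder vocabulary."""


class CoverageError(BraincostError):
    """The reference tables do not cover a (currency, year) or CPI year
    required by the corpus."""


class ConfigurationError(BraincostError):
    """Inconsistent run or disorder configuration (e.g. subtype weights
    that do not sum to one)."""


class CompletenessError(BraincostError):
    """A roll-up was requested over an incomplete disorder set."""
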