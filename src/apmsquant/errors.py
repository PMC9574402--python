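"""Exception hierarchy for the pipeline.

Stage code raises the most specific subclass it can; the CLI catches
:class:`ApmsError` and reports the stage that failed.
"""


class ApmsError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(ApmsError):
    """An input table is missing a required column or has a malformed header."""


class PsmValidationError(ApmsError):
    """A PSM row violates a contract (negative intensity, bad offset, ...).

    ``row`` is the 1-based data-row number (header and comment lines not
    counted) so the message points at the offending line of the input.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class FastaError(ApmsError):
    """Duplicate accession or empty sequence in a reference FASTA."""


class TableFormatError(ApmsError):
    """A malformed row in an interaction or annotation table (carries line number)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateRunError(ApmsError):
    """A run whose total intensity is zero cannot be globally normalized."""


class UnmappablePeptideError(ApmsError):
    """Peptide is not a substring of its protein's reference sequence."""


class AmbiguousPeptideError(ApmsError):
    """Peptide occurs at more than one position in the reference sequence."""


class StageError(ApmsError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
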