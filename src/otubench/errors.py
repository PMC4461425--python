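"""Exception hierarchy shared across the package."""


class OtubenchError(Exception):
    """Base class for all package-specific errors."""


class FastqParseError(OtubenchError):
    """Malformed FASTQ record (carries the 0-based record index)."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"FASTQ record {index}: {message}")


class FastaFormatError(OtubenchError):
    """FASTA record violating the nucleotide alphabet contract."""


class AlignmentFormatError(OtubenchError):
    """Aligned FASTA with ragged rows, or rows from different MSAs."""


class UndefinedIdentityError(OtubenchError):
    """Identity requested for an alignment with no comparable columns."""


class CapacityError(OtubenchError):
    """Distance-matrix clustering requested beyond the configured size guard."""


class GenerationError(OtubenchError):
    """Synthetic reference generation could not satisfy its constraints."""


class EvaluationError(OtubenchError):
    """Invalid input to classification or summary computation."""
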