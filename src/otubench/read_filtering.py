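"""Stringent and relaxed read-filtering regimes.

Both regimes share the rule order primer -> length (with trimming in the
stringent regime) -> ambiguous bases -> quality.  The stringent regime
trims every read to a fixed length and filters on the expected number of
errors of the trimmed read; the relaxed regime keeps variable-length
reads inside a window and filters on mean phred quality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .amplicon_io import Read

# IUPAC nucleotide degeneracy codes, used for primer matching only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: forward primer targeting the 18S V4 region (Uni18S)
UNI18S_FORWARD = "AGGGCAAKYCTGGTGCCAGC"


class FilterRegime(enum.Enum):
    STRINGENT = "stringent"
    RELAXED = "relaxed"


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for one filtering regime (defaults follow the benchmark)."""

    regime: FilterRegime
    forward_primer: str = UNI18S_FORWARD
    max_primer_mismatches: int = 0
    trim_length: int = 400          # stringent: fixed post-trim length
    min_length: int = 400           # stringent 400, relaxed 250
    max_length: int = 600           # relaxed only
    max_expected_error: float = 0.5  # stringent
    min_avg_quality: float = 20.0    # relaxed
    allow_ambiguous: bool = False
    strip_reverse_primer: bool = False
    reverse_primer: str | None = None

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.max_expected_error <= 0:
            raise ValueError("max_expected_error must be > 0")
        if self.max_primer_mismatches < 0:
            raise ValueError("max_primer_mismatches must be >= 0")

    @classmethod
    def stringent(cls, **overrides) -> "FilterParams":
        return cls(regime=FilterRegime.STRINGENT,
                   min_length=overrides.pop("min_length", 400),
                   **overrides)

    @classmethod
    def relaxed(cls, **overrides) -> "FilterParams":
        return cls(regime=FilterRegime.RELAXED,
                   min_length=overrides.pop("min_length", 250),
                   **overrides)


REJECTION_REASONS = (
    "primer_mismatch",
    "too_short_for_primer",
    "too_short",
    "too_long",
    "ambiguous_base",
    "expected_error",
    "avg_quality",
)


@dataclass
class FilterReport:
    """Per-reason rejection tallies; kept + sum(rejections) == input count."""

    input_reads: int = 0
    kept: int = 0
    primer_mismatch: int = 0
    too_short_for_primer: int = 0
    too_short: int = 0
    too_long: int = 0
    ambiguous_base: int = 0
    expected_error: int = 0
    avg_quality: int = 0

    def tally(self, reason: str) -> None:
        setattr(self, reason, getattr(self, reason) + 1)

    @property
    def total_rejected(self) -> int:
        return sum(getattr(self, r) for r in REJECTION_REASONS)

    def as_dict(self) -> dict[str, int]:
        d = {"input_reads": self.input_reads, "kept": self.kept}
        d.update({r: getattr(self, r) for r in REJECTION_REASONS})
        return d


def expected_error(qualities: Sequence[int]) -> float:
    """Expected number of erroneous bases: sum of 10^(-Q/10)."""
    return float(sum(10.0 ** (-q / 10.0) for q in qualities))


def mean_quality(qualities: Sequence[int]) -> float:
    if not qualities:
        return 0.0
    return sum(qualities) / len(qualities)


def _iupac_match(base: str, code: str) -> bool:
    return base in IUPAC.get(code, "")


def match_and_trim_primer(read: Read, primer: str,
                          max_mismatches: int = 0) -> tuple[Read | None, str | None]:
    """Match the 5' prefix against an IUPAC primer and strip it.

    Returns ``(trimmed_read, None)`` on success, else ``(None, reason)``
    with reason ``"too_short_for_primer"`` or ``"primer_mismatch"``.
    """
    if not primer:
        raise ValueError("primer must be nonempty")
    n = len(primer)
    if len(read.sequence) < n:
        return None, "too_short_for_primer"
    mismatches = 0
    for base, code in zip(read.sequence[:n], primer):
        if not _iupac_match(base, code):
            mismatches += 1
            if mismatches > max_mismatches:
                return None, "primer_mismatch"
    trimmed = Read(read.read_id, read.sequence[n:], list(read.qualities[n:]))
    return trimmed, None


def _locate_reverse_primer(seq: str, primer: str) -> int | None:
    # naive scan for an exact IUPAC match of the reverse primer inside the read
    n = len(primer)
    for start in range(len(seq) - n + 1):
        if all(_iupac_match(seq[start + k], primer[k]) for k in range(n)):
            return start
    return None


def apply_filter(reads: Iterable[Read],
                 params: FilterParams) -> tuple[list[Read], FilterReport]:
    """Apply one filtering regime; every input read is tallied exactly once."""
    report = FilterReport()
    kept: list[Read] = []
    stringent = params.regime is FilterRegime.STRINGENT
    for read in reads:
        report.input_reads += 1
        trimmed, reason = match_and_trim_primer(
            read, params.forward_primer, params.max_primer_mismatches)
        if trimmed is None:
            report.tally(reason)
            continue
        if params.strip_reverse_primer and params.reverse_primer:
            hit = _locate_reverse_primer(trimmed.sequence, params.reverse_primer)
            if hit is not None:
                trimmed = Read(trimmed.read_id, trimmed.sequence[:hit],
                               list(trimmed.qualities[:hit]))
        if stringent:
            if len(trimmed) < params.min_length:
                report.tally("too_short")
                continue
            trimmed = Read(trimmed.read_id,
                           trimmed.sequence[:params.trim_length],
                           list(trimmed.qualities[:params.trim_length]))
        else:
            if len(trimmed) < params.min_length:
                report.tally("too_short")
                continue
            if len(trimmed) > params.max_length:
                report.tally("too_long")
                continue
        if not params.allow_ambiguous and "N" in trimmed.sequence:
            report.tally("ambiguous_base")
            continue
        if stringent:
            if expected_error(trimmed.qualities) > params.max_expected_error:
                report.tally("expected_error")
                continue
        else:
            if mean_quality(trimmed.qualities) < params.min_avg_quality:
                report.tally("avg_quality")
                continue
        report.kept += 1
        kept.append(trimmed)
    assert report.kept + report.total_rejected == report.input_reads
    return kept, report
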