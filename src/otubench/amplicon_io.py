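"""Sequence I/O: FASTQ (phred+33), FASTA, and aligned FASTA.

All sequences are normalised on ingest to the single internal alphabet
``{A, C, G, T, N}``: lowercase is uppercased, ``U`` becomes ``T`` and any
other (IUPAC-degenerate) letter becomes ``N``.  Gap characters are only
legal in aligned FASTA.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio import SeqIO

from .errors import AlignmentFormatError, FastaFormatError, FastqParseError

PHRED_OFFSET = 33
MAX_QUALITY = 60
_VALID = frozenset("ACGTN")
# letters map to the internal alphabet; anything else is rejected
_LETTER_MAP = {c: (c if c in _VALID else ("T" if c == "U" else "N"))
               for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}


@dataclass
class Read:
    """One sequencing read with per-base phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be nonempty")
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedSeqRecord:
    """One row of a multiple sequence alignment (gap character '-')."""

    seq_id: str
    gapped_sequence: str

    def ungapped(self) -> str:
        return self.gapped_sequence.replace("-", "")


def sanitize_sequence(raw: str, *, where: str = "sequence") -> str:
    """Map a raw sequence string onto the internal {A,C,G,T,N} alphabet."""
    up = raw.upper()
    out = []
    for ch in up:
        mapped = _LETTER_MAP.get(ch)
        if mapped is None:
            raise FastaFormatError(f"{where}: illegal character {ch!r}")
        out.append(mapped)
    return "".join(out)


def decode_qualities(qual_string: str) -> list[int]:
    """Decode a phred+33 quality string to integer scores."""
    quals = [ord(c) - PHRED_OFFSET for c in qual_string]
    for q in quals:
        if q < 0 or q > MAX_QUALITY:
            raise ValueError(f"quality {q} outside [0, {MAX_QUALITY}]")
    return quals


def encode_qualities(qualities: Sequence[int]) -> str:
    """Encode integer phred scores as a phred+33 string."""
    for q in qualities:
        if q < 0 or q > MAX_QUALITY:
            raise ValueError(f"quality {q} outside [0, {MAX_QUALITY}]")
    return "".join(chr(q + PHRED_OFFSET) for q in qualities)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a 4-line phred+33 FASTQ file into an ordered list of reads."""
    reads: list[Read] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(index, str(exc)) from exc
            read_id = title.split(None, 1)[0] if title else ""
            if not read_id:
                raise FastqParseError(index, "empty read id")
            if read_id in seen:
                raise FastqParseError(index, f"duplicate read id {read_id!r}")
            seen.add(read_id)
            try:
                reads.append(Read(read_id, sanitize_sequence(seq, where=read_id),
                                  decode_qualities(qual)))
            except (ValueError, FastaFormatError) as exc:
                raise FastqParseError(index, str(exc)) from exc
            index += 1
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as canonical 4-line phred+33 FASTQ."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n"
                         f"{encode_qualities(read.qualities)}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse unaligned FASTA; ids are headers truncated at first whitespace."""
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if "-" in seq:
                raise FastaFormatError(
                    f"record {rec.id!r} contains '-': use read_aligned_fasta"
                )
            records.append((rec.id, sanitize_sequence(seq, where=rec.id)))
    return records


def _wrap(seq: str, width: int) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i:i + width]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``width`` columns."""
    with _open_text(path, "wt") as handle:
        for seq_id, seq in records:
            handle.write(f">{seq_id}\n")
            for line in _wrap(seq, width):
                handle.write(line + "\n")


def read_aligned_fasta(path: str | Path) -> list[AlignedSeqRecord]:
    """Parse aligned FASTA (gap '-'); all rows must have equal width."""
    rows: list[AlignedSeqRecord] = []
    width = None
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            gapped = str(rec.seq).upper()
            cleaned = []
            for ch in gapped:
                if ch == "-":
                    cleaned.append(ch)
                else:
                    mapped = _LETTER_MAP.get(ch)
                    if mapped is None:
                        raise AlignmentFormatError(
                            f"row {rec.id!r}: illegal character {ch!r}"
                        )
                    cleaned.append(mapped)
            gapped = "".join(cleaned)
            if width is None:
                width = len(gapped)
            elif len(gapped) != width:
                raise AlignmentFormatError(
                    f"row {rec.id!r} has width {len(gapped)}, expected {width}"
                )
            rows.append(AlignedSeqRecord(rec.id, gapped))
    return rows


def write_aligned_fasta(rows: Iterable[AlignedSeqRecord], path: str | Path,
                        width: int = 80) -> None:
    write_fasta(((r.seq_id, r.gapped_sequence) for r in rows), path, width)
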