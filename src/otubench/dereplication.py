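"""Dereplication of identical reads and the singleton policy."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .amplicon_io import Read, write_fasta


@dataclass
class UniqueSequence:
    """A dereplicated sequence with its abundance and member read ids."""

    sequence: str
    abundance: int
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.abundance != len(self.member_ids):
            raise ValueError("abundance must equal len(member_ids)")

    @property
    def label(self) -> str:
        """Representative id: the first member read id."""
        return self.member_ids[0]


def dereplicate(reads: Iterable[Read]) -> list[UniqueSequence]:
    """Collapse reads with identical full-length sequences.

    Output is sorted by decreasing abundance, ties broken by sequence
    lexicographic order; the sum of abundances equals the input count.
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.sequence, []).append(read.read_id)
    uniques = [UniqueSequence(seq, len(ids), ids) for seq, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def remove_singletons(uniques: Iterable[UniqueSequence]) -> list[UniqueSequence]:
    """Keep only unique sequences with abundance >= 2, preserving order."""
    return [u for u in uniques if u.abundance >= 2]


def write_unique_fasta(uniques: Iterable[UniqueSequence],
                       path: str | Path) -> None:
    """Write uniques as FASTA with USEARCH-style ';size=N' annotations."""
    write_fasta(((f"{u.label};size={u.abundance}", u.sequence)
                 for u in uniques), path)


def membership_map(uniques: Iterable[UniqueSequence]) -> dict[str, list[str]]:
    """Map each unique's representative id to its member read ids."""
    return {u.label: list(u.member_ids) for u in uniques}
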