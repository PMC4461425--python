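"""Pairwise global alignment and identity under three gap definitions.

The identity of an aligned pair is computed from column counts:

* ``NO_GAPS``  — gap columns are excluded: ``M / (M + X)``
* ``ONE_GAP``  — every gap *run* is one difference: ``M / (M + X + R)``
* ``EACH_GAP`` — every gap *column* is a difference: ``M / (M + X + C)``

where M and X are match and mismatch columns.  A gap run is a maximal
block of consecutive ``-`` within one sequence; a run touching the first
or last alignment column is *terminal*.  The terminal policy decides
whether terminal runs/columns enter R and C (``COUNT``, the behaviour of
the clustering tools being modelled) or are treated as missing data
(``EXCLUDE``).  Divergence is ``1 - identity``.

Alignments are optimal Needleman-Wunsch with affine gap costs (a run of
length k costs ``gap_open + (k - 1) * gap_extend``).  Terminal gaps are
scored separately and cheaply (default -1 per column, no opening cost),
so length variants align with explicit terminal gap runs instead of
scattering internal gaps, while completely unrelated sequences still
prefer a maximal-overlap alignment.  Making terminal gaps entirely free
is tempting but degenerate: the optimum for an unrelated pair then
shrinks the aligned overlap to a single chance match, which would give
near-perfect NO_GAPS identity to arbitrary sequence pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .amplicon_io import AlignedSeqRecord
from .errors import AlignmentFormatError, UndefinedIdentityError


class GapDefinition(enum.Enum):
    NO_GAPS = "no_gaps"
    ONE_GAP = "one_gap"
    EACH_GAP = "each_gap"


class TerminalPolicy(enum.Enum):
    COUNT = "count"
    EXCLUDE = "exclude"


@dataclass(frozen=True)
class IdentityConfig:
    definition: GapDefinition = GapDefinition.EACH_GAP
    terminal_policy: TerminalPolicy = TerminalPolicy.COUNT


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring.

    Internal gap runs of length k cost ``gap_open + (k-1) * gap_extend``;
    terminal runs cost ``end_gap_open + (k-1) * end_gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    end_gap_open: float = -1.0
    end_gap_extend: float = -1.0

    @classmethod
    def free_end_gaps(cls, **overrides) -> "ScoringScheme":
        """End gaps cost nothing (degenerate for unrelated pairs)."""
        return cls(end_gap_open=0.0, end_gap_extend=0.0, **overrides)

    @classmethod
    def full_global(cls, **overrides) -> "ScoringScheme":
        """End gaps penalised like internal gaps (classic global mode)."""
        base = cls(**overrides)
        return cls(match=base.match, mismatch=base.mismatch,
                   gap_open=base.gap_open, gap_extend=base.gap_extend,
                   end_gap_open=base.gap_open, end_gap_extend=base.gap_extend)


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignedPair:
    """An aligned sequence pair; no column may be a gap in both rows."""

    gapped_a: str
    gapped_b: str

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise AlignmentFormatError("aligned rows must have equal length")
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca == "-" and cb == "-":
                raise AlignmentFormatError("column gapped in both sequences")

    def ungapped_a(self) -> str:
        return self.gapped_a.replace("-", "")

    def ungapped_b(self) -> str:
        return self.gapped_b.replace("-", "")


@dataclass(frozen=True)
class AlignmentStats:
    """Column/run counts of an aligned pair, split internal vs terminal."""

    M: int              # match columns
    X: int              # mismatch columns
    C_int: int          # internal gap columns
    R_int: int          # internal gap runs
    C_term: int         # terminal gap columns
    R_term: int         # terminal gap runs

    @property
    def alignment_length(self) -> int:
        return self.M + self.X + self.C_int + self.C_term

    @property
    def aligned_overlap_length(self) -> int:
        """Columns excluding terminal gaps (M + X + internal gap columns)."""
        return self.M + self.X + self.C_int


_ALIGNER_CACHE: dict[ScoringScheme, Align.PairwiseAligner] = {}


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        aligner.open_gap_score = scoring.gap_open
        aligner.extend_gap_score = scoring.gap_extend
        aligner.open_end_insertion_score = scoring.end_gap_open
        aligner.extend_end_insertion_score = scoring.end_gap_extend
        aligner.open_end_deletion_score = scoring.end_gap_open
        aligner.extend_end_deletion_score = scoring.end_gap_extend
        aligner.wildcard = "N"
        _ALIGNER_CACHE[scoring] = aligner
    return aligner


def global_align(a: str, b: str,
                 scoring: ScoringScheme = DEFAULT_SCORING) -> AlignedPair:
    """Optimal global alignment of two nucleotide sequences.

    Traceback ties are broken deterministically (the first optimal
    alignment reported by the underlying dynamic program is used).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    alignment = _aligner(scoring).align(a, b)[0]
    return AlignedPair(alignment[0], alignment[1])


def global_align_score(a: str, b: str,
                       scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Optimal global alignment score (no traceback)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return float(_aligner(scoring).score(a, b))


def _gap_runs(gapped: str) -> list[tuple[int, int]]:
    """(start, end) half-open spans of maximal '-' runs in one row."""
    runs = []
    start = None
    for i, ch in enumerate(gapped):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(gapped)))
    return runs


def alignment_stats(pair: AlignedPair, *, n_as_match: bool = True) -> AlignmentStats:
    """Count match/mismatch/gap columns and gap runs of an aligned pair.

    A gap run touching the first or last alignment column is terminal.
    Columns where either sequence has 'N' count as matches when
    ``n_as_match`` is true (the default), else as mismatches.
    """
    a, b = pair.gapped_a, pair.gapped_b
    length = len(a)
    m = x = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb or (n_as_match and (ca == "N" or cb == "N")):
            m += 1
        else:
            x += 1
    c_int = r_int = c_term = r_term = 0
    for row in (a, b):
        for start, end in _gap_runs(row):
            if start == 0 or end == length:
                c_term += end - start
                r_term += 1
            else:
                c_int += end - start
                r_int += 1
    return AlignmentStats(M=m, X=x, C_int=c_int, R_int=r_int,
                          C_term=c_term, R_term=r_term)


def identity(stats: AlignmentStats, cfg: IdentityConfig) -> float:
    """Fractional identity of an aligned pair under one gap definition."""
    comparable = stats.M + stats.X
    if comparable == 0:
        raise UndefinedIdentityError("alignment has no match/mismatch columns")
    count_terminal = cfg.terminal_policy is TerminalPolicy.COUNT
    if cfg.definition is GapDefinition.NO_GAPS:
        denom = comparable
    elif cfg.definition is GapDefinition.ONE_GAP:
        runs = stats.R_int + (stats.R_term if count_terminal else 0)
        denom = comparable + runs
    else:  # EACH_GAP
        cols = stats.C_int + (stats.C_term if count_terminal else 0)
        denom = comparable + cols
    return stats.M / denom


def divergence(stats: AlignmentStats, cfg: IdentityConfig) -> float:
    return 1.0 - identity(stats, cfg)


# ---------------------------------------------------------------------------
# cached align-and-count used heavily by clustering and evaluation

_STATS_CACHE: dict[tuple[str, str, ScoringScheme], AlignmentStats] = {}


def align_stats(a: str, b: str,
                scoring: ScoringScheme = DEFAULT_SCORING) -> AlignmentStats:
    """Alignment stats of the optimal global alignment of ``a`` and ``b``.

    Results are cached on the (unordered) sequence pair; the counts are
    symmetric under swapping the two sequences.
    """
    if b < a:
        a, b = b, a
    key = (a, b, scoring)
    stats = _STATS_CACHE.get(key)
    if stats is None:
        stats = alignment_stats(global_align(a, b, scoring))
        _STATS_CACHE[key] = stats
    return stats


def clear_alignment_cache() -> None:
    _STATS_CACHE.clear()


def pair_divergence(a: str, b: str, cfg: IdentityConfig,
                    scoring: ScoringScheme = DEFAULT_SCORING,
                    on_undefined: str = "raise") -> float:
    """Divergence (1 - identity) of two unaligned sequences.

    ``on_undefined`` controls alignments without comparable columns:
    ``"raise"`` (default) or ``"max"`` to report divergence 1.0.
    """
    if a == b:
        return 0.0
    try:
        return divergence(align_stats(a, b, scoring), cfg)
    except UndefinedIdentityError:
        if on_undefined == "max":
            return 1.0
        raise


# ---------------------------------------------------------------------------
# MSA-based identities (hierarchical clustering input)

def msa_pair(row_i: AlignedSeqRecord, row_j: AlignedSeqRecord) -> AlignedPair:
    """Project two MSA rows to a pairwise alignment (drop both-gap columns)."""
    gi, gj = row_i.gapped_sequence, row_j.gapped_sequence
    if len(gi) != len(gj):
        raise AlignmentFormatError(
            f"rows {row_i.seq_id!r}/{row_j.seq_id!r} have unequal widths")
    kept_i = []
    kept_j = []
    for ci, cj in zip(gi, gj):
        if ci == "-" and cj == "-":
            continue
        kept_i.append(ci)
        kept_j.append(cj)
    return AlignedPair("".join(kept_i), "".join(kept_j))


def msa_pair_identity(row_i: AlignedSeqRecord, row_j: AlignedSeqRecord,
                      cfg: IdentityConfig, *, n_as_match: bool = True) -> float:
    """Identity of two rows of one MSA under the given configuration."""
    stats = alignment_stats(msa_pair(row_i, row_j), n_as_match=n_as_match)
    return identity(stats, cfg)


# ---------------------------------------------------------------------------
# distance matrices

def distance_matrix(seqs: Sequence[str], cfg: IdentityConfig,
                    scoring: ScoringScheme = DEFAULT_SCORING) -> np.ndarray:
    """Symmetric divergence matrix from all-pairs global alignment."""
    n = len(seqs)
    if n < 2:
        raise ValueError("distance_matrix requires at least 2 sequences")
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pair_divergence(seqs[i], seqs[j], cfg, scoring)
            except UndefinedIdentityError as exc:
                raise UndefinedIdentityError(
                    f"undefined identity for pair ({i}, {j}): {exc}") from exc
            dmat[i, j] = dmat[j, i] = d
    return dmat


def distance_matrix_from_msa(rows: Sequence[AlignedSeqRecord],
                             cfg: IdentityConfig) -> np.ndarray:
    """Symmetric divergence matrix from rows of one MSA (vectorised)."""
    n = len(rows)
    if n < 2:
        raise ValueError("distance_matrix requires at least 2 rows")
    width = len(rows[0].gapped_sequence)
    for row in rows:
        if len(row.gapped_sequence) != width:
            raise AlignmentFormatError(f"ragged MSA row {row.seq_id!r}")
    enc = np.frombuffer(
        "".join(r.gapped_sequence for r in rows).encode("ascii"), dtype=np.uint8
    ).reshape(n, width)
    gap = ord("-")
    n_code = ord("N")
    is_gap = enc == gap
    is_n = enc == n_code
    count_terminal = cfg.terminal_policy is TerminalPolicy.COUNT
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(is_gap[i] & is_gap[j])
            a = enc[i, keep]
            b = enc[j, keep]
            ga = a == gap
            gb = b == gap
            ungapped = ~ga & ~gb
            m = int(np.count_nonzero(
                ungapped & ((a == b) | is_n[i, keep] | is_n[j, keep])))
            comparable = int(np.count_nonzero(ungapped))
            x = comparable - m
            if comparable == 0:
                raise UndefinedIdentityError(
                    f"undefined identity for pair ({i}, {j})")
            if cfg.definition is GapDefinition.NO_GAPS:
                denom = comparable
            else:
                c_int = r_int = c_term = r_term = 0
                for mask in (ga, gb):
                    spans = _mask_runs(mask)
                    for start, end in spans:
                        if start == 0 or end == mask.size:
                            c_term += end - start
                            r_term += 1
                        else:
                            c_int += end - start
                            r_int += 1
                if cfg.definition is GapDefinition.ONE_GAP:
                    denom = comparable + r_int + (r_term if count_terminal else 0)
                else:
                    denom = comparable + c_int + (c_term if count_terminal else 0)
            dmat[i, j] = dmat[j, i] = 1.0 - m / denom
    return dmat


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open spans of True runs in a boolean vector."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def write_phylip_lower(dmat: np.ndarray, labels: Sequence[str],
                       path: str | Path) -> None:
    """Write a distance matrix in mothur's lower-triangle phylip dialect."""
    n = dmat.shape[0]
    with open(path, "w") as handle:
        handle.write(f"{n}\n")
        for i in range(n):
            cells = "\t".join(f"{dmat[i, j]:.6f}" for j in range(i))
            handle.write(labels[i] + ("\t" + cells if cells else "") + "\n")
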