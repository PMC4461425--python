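"""OTU classification against a reference set and accuracy metrics.

Each OTU centroid is aligned end-gap-free against every reference
sequence; the best hit is the reference with maximal identity computed
over the aligned overlap with gap columns excluded.  A hit is positive
only if it reaches the identity and overlap thresholds (defaults 90%
and 200 nt).  Precision is the number of distinct reference species
recovered divided by the total number of OTUs produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .amplicon_io import read_fasta
from .clustering import OTU
from .errors import EvaluationError
from .pairwise_identity import (
    DEFAULT_SCORING,
    GapDefinition,
    IdentityConfig,
    ScoringScheme,
    align_stats,
    identity as _identity,
)

UNCLASSIFIED = "UNCLASSIFIED"

_NO_GAPS = IdentityConfig(definition=GapDefinition.NO_GAPS)


@dataclass(frozen=True)
class ReferenceRecord:
    species_name: str
    sequence: str


@dataclass(frozen=True)
class Classification:
    otu_id: str
    best_species: str
    best_identity: float
    alignment_overlap: int
    tied: bool = False

    @property
    def is_classified(self) -> bool:
        return self.best_species != UNCLASSIFIED


@dataclass(frozen=True)
class EvaluationSummary:
    n_otus: int
    n_matched_otus: int
    n_species_detected: int
    precision: float
    species_detection: float


def load_references(path: str | Path) -> list[ReferenceRecord]:
    """Load a reference FASTA; the species name is the first header token."""
    records = [ReferenceRecord(seq_id, seq) for seq_id, seq in read_fasta(path)]
    names = [r.species_name for r in records]
    if len(set(names)) != len(names):
        raise EvaluationError("duplicate species names in reference set")
    return records


def validate_references(refs: Sequence[ReferenceRecord],
                        divergence_threshold: float = 0.03,
                        scoring: ScoringScheme = DEFAULT_SCORING,
                        ) -> list[tuple[str, str, float]]:
    """Warn about reference pairs closer than the clustering threshold.

    Returns the offending (species_a, species_b, divergence) triples;
    such species cannot be distinguished at the threshold and should be
    removed by the caller.
    """
    offenders = []
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            stats = align_stats(refs[i].sequence, refs[j].sequence, scoring)
            d = 1.0 - _identity(stats, _NO_GAPS)
            if d <= divergence_threshold:
                offenders.append((refs[i].species_name,
                                  refs[j].species_name, d))
    if offenders:
        warnings.warn(
            f"{len(offenders)} reference pair(s) within the "
            f"{divergence_threshold:.0%} divergence threshold: "
            + ", ".join(f"{a}/{b}" for a, b, _ in offenders),
            stacklevel=2)
    return offenders


def classify_otus(otus: Sequence[OTU], refs: Sequence[ReferenceRecord],
                  min_identity: float = 0.90, min_overlap: int = 200,
                  scoring: ScoringScheme = DEFAULT_SCORING,
                  overlap_mode: str = "nonterminal") -> list[Classification]:
    """Best-hit classification of OTU centroids against the references.

    ``overlap_mode`` selects what the overlap-length rule counts:
    ``"nonterminal"`` (default) all non-terminal-gap columns, ``"all"``
    every alignment column.
    """
    if not refs:
        raise EvaluationError("empty reference set")
    if overlap_mode not in ("nonterminal", "all"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    ordered_refs = sorted(refs, key=lambda r: r.species_name)
    results = []
    for otu in otus:
        best: tuple[float, int, str] | None = None
        tied = False
        for ref in ordered_refs:
            stats = align_stats(otu.centroid, ref.sequence, scoring)
            if stats.M + stats.X == 0:
                continue
            ident = _identity(stats, _NO_GAPS)
            overlap = (stats.aligned_overlap_length
                       if overlap_mode == "nonterminal"
                       else stats.alignment_length)
            if best is None or ident > best[0]:
                best = (ident, overlap, ref.species_name)
                tied = False
            elif ident == best[0]:
                tied = True  # alphabetically first species kept
        if (best is not None and best[0] >= min_identity
                and best[1] >= min_overlap):
            results.append(Classification(otu.otu_id, best[2], best[0],
                                          best[1], tied))
        else:
            results.append(Classification(
                otu.otu_id, UNCLASSIFIED,
                best[0] if best else 0.0,
                best[1] if best else 0, tied))
    return results


def summarize(classifications: Sequence[Classification],
              refs: Sequence[ReferenceRecord],
              n_otus: int) -> EvaluationSummary:
    """Aggregate classifications into the benchmark's accuracy metrics."""
    if n_otus == 0:
        raise EvaluationError("precision undefined for zero OTUs")
    matched = [c for c in classifications if c.is_classified]
    species = {c.best_species for c in matched}
    return EvaluationSummary(
        n_otus=n_otus,
        n_matched_otus=len(matched),
        n_species_detected=len(species),
        precision=len(species) / n_otus,
        species_detection=len(species) / len(refs),
    )


def write_classification_tsv(classifications: Sequence[Classification],
                             path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("otu_id\tspecies\tidentity\toverlap\ttied\n")
        for c in classifications:
            handle.write(f"{c.otu_id}\t{c.best_species}\t"
                         f"{c.best_identity:.4f}\t{c.alignment_overlap}\t"
                         f"{int(c.tied)}\n")


# ---------------------------------------------------------------------------
# ground-truth audit against simulator labels

@dataclass(frozen=True)
class AuditReport:
    per_species_otus: dict[str, int]
    oversplit_species: int      # species represented by >= 2 OTUs
    undersplit_otus: int        # OTUs mixing reads of >= 2 species
    chimera_otus: int           # OTUs whose member reads are mostly chimeric


def ground_truth_audit(otus: Sequence[OTU],
                       ground_truth: dict) -> AuditReport:
    """Attribute OTUs to originating species via read-level labels.

    Every member read id of every OTU must be present in the ground
    truth.  An OTU is attributed to the species providing the majority
    of its non-chimeric reads; chimeric reads are tallied separately.
    """
    per_species: dict[str, int] = {}
    undersplit = 0
    chimera_otus = 0
    for otu in otus:
        species_counts: dict[str, int] = {}
        n_chimeric = 0
        n_reads = 0
        for member in otu.members:
            for read_id in member.member_ids:
                entry = ground_truth.get(read_id)
                if entry is None:
                    raise EvaluationError(
                        f"read {read_id!r} missing from ground truth")
                n_reads += 1
                if entry.is_chimera:
                    n_chimeric += 1
                else:
                    species_counts[entry.species] = (
                        species_counts.get(entry.species, 0) + 1)
        if n_chimeric * 2 > n_reads:
            chimera_otus += 1
            continue
        if len(species_counts) >= 2:
            undersplit += 1
        majority = max(sorted(species_counts), key=species_counts.get)
        per_species[majority] = per_species.get(majority, 0) + 1
    oversplit = sum(1 for n in per_species.values() if n >= 2)
    return AuditReport(per_species, oversplit, undersplit, chimera_otus)
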