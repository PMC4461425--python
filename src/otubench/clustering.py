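"""OTU clustering: greedy centroid-based and hierarchical agglomerative.

Greedy clustering processes unique sequences in decreasing-abundance
order; each sequence joins the first (or best) existing centroid within
the divergence threshold, otherwise it founds a new cluster.  Centroids
are immutable once created.  Hierarchical clustering agglomerates a full
pairwise distance matrix under a chosen linkage and applies every merge
whose linkage distance is at or below the threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .amplicon_io import AlignedSeqRecord, write_fasta
from .dereplication import UniqueSequence
from .errors import CapacityError
from .pairwise_identity import (
    DEFAULT_SCORING,
    GapDefinition,
    IdentityConfig,
    ScoringScheme,
    TerminalPolicy,
    distance_matrix,
    distance_matrix_from_msa,
    pair_divergence,
)


class ClusterAlgorithm(enum.Enum):
    GREEDY = "greedy"
    HIERARCHICAL = "hierarchical"


class Linkage(enum.Enum):
    AVERAGE = "average"
    FURTHEST = "furthest"
    NEAREST = "nearest"


_SCIPY_METHOD = {Linkage.AVERAGE: "average",
                 Linkage.FURTHEST: "complete",
                 Linkage.NEAREST: "single"}


class AcceptMode(enum.Enum):
    FIRST_HIT = "first_hit"
    BEST_HIT = "best_hit"


@dataclass(frozen=True)
class ClusterConfig:
    algorithm: ClusterAlgorithm = ClusterAlgorithm.GREEDY
    divergence_threshold: float = 0.03
    identity_cfg: IdentityConfig = field(default_factory=IdentityConfig)
    linkage: Linkage = Linkage.AVERAGE
    accept_mode: AcceptMode = AcceptMode.FIRST_HIT
    max_matrix_size: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence_threshold < 1.0:
            raise ValueError("divergence_threshold must be in (0, 1)")


@dataclass
class OTU:
    otu_id: str
    centroid: str
    members: list[UniqueSequence]
    total_abundance: int


def _min_divergence_bound(len_a: int, len_b: int, cfg: IdentityConfig) -> float:
    """Exact lower bound on divergence from the length difference alone.

    Under EACH_GAP with terminal gaps counted, any alignment of the pair
    has at least ``|len_a - len_b|`` gap columns and at most
    ``min(len_a, len_b)`` match+mismatch columns, so
    divergence >= delta / (min + delta).  Used as a cheap exact screen;
    other definitions give no useful bound.
    """
    if (cfg.definition is not GapDefinition.EACH_GAP
            or cfg.terminal_policy is not TerminalPolicy.COUNT):
        return 0.0
    delta = abs(len_a - len_b)
    if delta == 0:
        return 0.0
    shorter = min(len_a, len_b)
    return delta / (shorter + delta)


def greedy_cluster(uniques: Sequence[UniqueSequence], cfg: ClusterConfig,
                   scoring: ScoringScheme = DEFAULT_SCORING) -> list[OTU]:
    """Single-pass abundance-ordered centroid clustering."""
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    centroids: list[str] = []
    members: list[list[UniqueSequence]] = []
    threshold = cfg.divergence_threshold
    for unique in ordered:
        chosen = None
        best_d = None
        for idx, centroid in enumerate(centroids):
            if _min_divergence_bound(len(unique.sequence), len(centroid),
                                     cfg.identity_cfg) > threshold:
                continue
            d = pair_divergence(unique.sequence, centroid,
                                cfg.identity_cfg, scoring,
                                on_undefined="max")
            if d <= threshold:
                if cfg.accept_mode is AcceptMode.FIRST_HIT:
                    chosen = idx
                    break
                if best_d is None or d < best_d:
                    best_d = d
                    chosen = idx
        if chosen is None:
            centroids.append(unique.sequence)
            members.append([unique])
        else:
            members[chosen].append(unique)
    return _build_otus(members, centroid_rule="founder")


def hierarchical_cluster(dmat: np.ndarray,
                         uniques: Sequence[UniqueSequence],
                         cfg: ClusterConfig) -> list[OTU]:
    """Agglomerative clustering of a precomputed divergence matrix.

    Merges with linkage distance <= the divergence threshold are applied
    and none beyond (hard cut at merge height).
    """
    dmat = np.asarray(dmat, dtype=float)
    if dmat.ndim != 2 or dmat.shape[0] != dmat.shape[1]:
        raise ValueError("distance matrix must be square")
    if dmat.shape[0] != len(uniques):
        raise ValueError("matrix size does not match number of sequences")
    if np.isnan(dmat).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dmat, dmat.T):
        raise ValueError("distance matrix is not symmetric")
    n = dmat.shape[0]
    if n == 1:
        labels = [1]
    else:
        condensed = squareform(dmat, checks=False)
        tree = linkage(condensed, method=_SCIPY_METHOD[cfg.linkage])
        labels = fcluster(tree, t=cfg.divergence_threshold,
                          criterion="distance")
    groups: dict[int, list[UniqueSequence]] = {}
    for label, unique in zip(labels, uniques):
        groups.setdefault(int(label), []).append(unique)
    return _build_otus(list(groups.values()), centroid_rule="most_abundant")


def _build_otus(member_groups: list[list[UniqueSequence]],
                centroid_rule: str) -> list[OTU]:
    otus = []
    for group in member_groups:
        ordered = sorted(group, key=lambda u: (-u.abundance, u.sequence))
        if centroid_rule == "founder":
            centroid = group[0].sequence  # creation order: founder first
        else:
            centroid = ordered[0].sequence
        otus.append(OTU("", centroid, ordered,
                        sum(u.abundance for u in ordered)))
    otus.sort(key=lambda o: (-o.total_abundance, o.centroid))
    for i, otu in enumerate(otus, start=1):
        otu.otu_id = f"OTU_{i:04d}"
    return otus


def cluster(uniques: Sequence[UniqueSequence], cfg: ClusterConfig,
            msa: Sequence[AlignedSeqRecord] | None = None,
            scoring: ScoringScheme = DEFAULT_SCORING) -> list[OTU]:
    """Dispatch to greedy or hierarchical clustering.

    Hierarchical mode derives distances from the supplied MSA when given
    (rows matched to uniques by their ungapped sequence), else from
    all-pairs global alignment; it refuses inputs larger than
    ``max_matrix_size``.
    """
    if not uniques:
        return []
    if cfg.algorithm is ClusterAlgorithm.GREEDY:
        return greedy_cluster(uniques, cfg, scoring)
    n = len(uniques)
    if n > cfg.max_matrix_size:
        raise CapacityError(
            f"{n} sequences exceed the distance-matrix guard "
            f"({cfg.max_matrix_size}); a full pairwise matrix is infeasible")
    if n == 1:
        return _build_otus([[uniques[0]]], centroid_rule="most_abundant")
    if msa is not None:
        by_seq = {row.ungapped(): row for row in msa}
        rows = []
        for unique in uniques:
            row = by_seq.get(unique.sequence)
            if row is None:
                raise ValueError(
                    f"MSA has no row matching unique {unique.label!r}")
            rows.append(row)
        dmat = distance_matrix_from_msa(rows, cfg.identity_cfg)
    else:
        dmat = distance_matrix([u.sequence for u in uniques],
                               cfg.identity_cfg, scoring)
    return hierarchical_cluster(dmat, uniques, cfg)


# ---------------------------------------------------------------------------
# output writers

def write_otu_fasta(otus: Sequence[OTU], path: str | Path) -> None:
    """OTU representative sequences with ';size=' abundance annotations."""
    write_fasta(((f"{o.otu_id};size={o.total_abundance}", o.centroid)
                 for o in otus), path)


def write_membership_tsv(otus: Sequence[OTU], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("otu_id\tmember_id\tabundance\n")
        for otu in otus:
            for member in otu.members:
                handle.write(f"{otu.otu_id}\t{member.label}\t"
                             f"{member.abundance}\n")


def write_mothur_list(otus: Sequence[OTU], threshold: float,
                      path: str | Path) -> None:
    """One mothur-style list line: label, #OTUs, comma-joined members."""
    cells = [",".join(m.label for m in otu.members) for otu in otus]
    with open(path, "w") as handle:
        handle.write("\t".join([f"{threshold:g}", str(len(otus))] + cells)
                     + "\n")
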