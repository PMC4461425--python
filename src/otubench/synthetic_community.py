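"""Synthetic mock community: references, error-bearing reads, ground truth.

Emulates pyrosequencing of a length-variable hypervariable marker:
species templates differ both in composition and in length (terminal-gap
territory for the clustering stage), reads carry substitution, indel and
homopolymer-slip errors plus occasional two-parent chimeras, and
per-base qualities decay toward the 3' end.  Every read is labelled in
a ground-truth table so downstream OTUs can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .amplicon_io import Read
from .dereplication import UniqueSequence
from .errors import GenerationError
from .evaluation import ReferenceRecord
from .pairwise_identity import (
    GapDefinition,
    IdentityConfig,
    pair_divergence,
)
from .read_filtering import IUPAC, UNI18S_FORWARD

_BASES = "ACGT"
_NO_GAPS = IdentityConfig(definition=GapDefinition.NO_GAPS)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the simulated reference community."""

    n_species: int = 43
    length_range: tuple[int, int] = (380, 600)
    min_interspecies_divergence: float = 0.06
    copies_per_species: tuple[int, int] = (1, 3)
    copy_sub_rate: float = 0.005
    copy_indel_rate: float = 0.001
    # slippage-style block indels between intragenomic copies: length
    # variation between rRNA gene copies is what oversplits species under
    # gap-heavy identity definitions
    copy_block_indel_prob: float = 0.3
    copy_block_indel_size: tuple[int, int] = (10, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if not 0 < self.min_interspecies_divergence < 1:
            raise ValueError("min_interspecies_divergence must be in (0, 1)")


@dataclass(frozen=True)
class ErrorModel:
    """Per-read error process of the simulated sequencer."""

    sub_rate: float = 0.001
    indel_rate: float = 0.0002
    homopolymer_slip_prob: float = 0.002   # per run of length >= 3
    chimera_rate: float = 0.005
    quality_mean_start: float = 35.0
    quality_mean_end: float = 25.0

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(sub_rate=0.0, indel_rate=0.0, homopolymer_slip_prob=0.0,
                   chimera_rate=0.0)


@dataclass(frozen=True)
class GroundTruthEntry:
    species: str
    copy_index: int
    is_chimera: bool
    chimera_parents: tuple[str, str] | None
    n_errors_injected: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float) -> tuple[str, int]:
    """i.i.d. per-base substitution/indel edits; returns (sequence, n_edits)."""
    out: list[str] = []
    n_edits = 0
    for base in seq:
        r = rng.random()
        if r < indel_rate:
            n_edits += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append(_BASES[rng.integers(4)])  # insertion
        elif r < indel_rate + sub_rate:
            n_edits += 1
            choices = [b for b in _BASES if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out), n_edits


def _adjust_length(rng: np.random.Generator, seq: str, target: int) -> str:
    """Insert or delete random blocks until the sequence has target length."""
    seq_list = list(seq)
    while len(seq_list) != target:
        delta = target - len(seq_list)
        block = min(abs(delta), max(1, abs(delta) // 2 + 1))
        pos = int(rng.integers(0, len(seq_list)))
        if delta > 0:
            insert = [_BASES[rng.integers(4)] for _ in range(block)]
            seq_list[pos:pos] = insert
        else:
            del seq_list[pos:pos + block]
        if not seq_list:  # degenerate guard
            seq_list = list(_random_sequence(rng, target))
    return "".join(seq_list)


def _pairwise_divergence_no_gaps(a: str, b: str) -> float:
    return pair_divergence(a, b, _NO_GAPS, on_undefined="max")


def generate_references(
        spec: CommunitySpec,
) -> tuple[list[ReferenceRecord], dict[str, list[str]]]:
    """Generate species templates and intragenomic copies.

    Templates are derived by mutating/length-editing ancestors from a
    small seeded pool and accepted only if their divergence from every
    previously accepted template is at least the configured minimum.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    n_ancestors = max(1, spec.n_species // 8)
    mean_len = (lo + hi) // 2
    ancestors = [_random_sequence(rng, mean_len) for _ in range(n_ancestors)]
    refs: list[ReferenceRecord] = []
    templates: dict[str, list[str]] = {}
    max_attempts = 50 * spec.n_species
    attempts = 0
    # substitution load well above the divergence floor so acceptance is fast
    sub_load = max(0.12, 2.0 * spec.min_interspecies_divergence)
    while len(refs) < spec.n_species:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {spec.n_species} species at divergence "
                f">= {spec.min_interspecies_divergence} within "
                f"{max_attempts} attempts")
        ancestor = ancestors[int(rng.integers(n_ancestors))]
        target_len = int(rng.integers(lo, hi + 1))
        candidate, _ = _mutate(rng, ancestor, sub_load, 0.002)
        candidate = _adjust_length(rng, candidate, target_len)
        if any(_pairwise_divergence_no_gaps(candidate, r.sequence)
               < spec.min_interspecies_divergence for r in refs):
            continue
        name = f"species_{len(refs) + 1:03d}"
        refs.append(ReferenceRecord(name, candidate))
        n_copies = int(rng.integers(spec.copies_per_species[0],
                                    spec.copies_per_species[1] + 1))
        copies = [candidate]
        for _ in range(n_copies - 1):
            copy, _ = _mutate(rng, candidate, spec.copy_sub_rate,
                              spec.copy_indel_rate)
            if rng.random() < spec.copy_block_indel_prob:
                size = int(rng.integers(spec.copy_block_indel_size[0],
                                        spec.copy_block_indel_size[1] + 1))
                pos = int(rng.integers(0, max(1, len(copy) - size)))
                if rng.random() < 0.5 and len(copy) - size >= 50:
                    copy = copy[:pos] + copy[pos + size:]        # contraction
                else:
                    block = _random_sequence(rng, size)
                    copy = copy[:pos] + block + copy[pos:]       # expansion
            copies.append(copy)
        templates[name] = copies
    return refs, templates


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((start, i))
            start = i
    return runs


def _apply_errors(rng: np.random.Generator, seq: str,
                  err: ErrorModel) -> tuple[str, int]:
    """Substitutions, indels and homopolymer slips; returns (seq, n_errors)."""
    n_errors = 0
    # homopolymer slips first (they act on runs of the template)
    if err.homopolymer_slip_prob > 0:
        shift = 0
        seq_list = list(seq)
        for start, end in _homopolymer_runs(seq):
            if rng.random() < err.homopolymer_slip_prob:
                n_errors += 1
                if rng.random() < 0.5:
                    del seq_list[start + shift]
                    shift -= 1
                else:
                    seq_list.insert(start + shift, seq[start])
                    shift += 1
        seq = "".join(seq_list)
    if err.sub_rate > 0 or err.indel_rate > 0:
        seq, n_point = _mutate(rng, seq, err.sub_rate, err.indel_rate)
        n_errors += n_point
    return seq, n_errors


def _realize_primer(rng: np.random.Generator, primer: str) -> str:
    """Resolve IUPAC degeneracies to a concrete primer sequence."""
    out = []
    for code in primer:
        options = IUPAC[code]
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


def _qualities(rng: np.random.Generator, length: int,
               err: ErrorModel) -> list[int]:
    if length == 0:
        return []
    ramp = np.linspace(err.quality_mean_start, err.quality_mean_end, length)
    jitter = rng.integers(-2, 3, size=length)
    return [int(q) for q in np.clip(np.rint(ramp + jitter), 2, 41)]


def simulate_reads(templates: dict[str, list[str]],
                   n_reads: int,
                   err: ErrorModel,
                   seed: int,
                   abundance_model: str = "uniform",
                   lognormal_sigma: float = 1.2,
                   primer: str = UNI18S_FORWARD,
                   dropout_species: Sequence[str] = (),
                   ) -> tuple[list[Read], dict[str, GroundTruthEntry]]:
    """Draw labelled reads from the community under an abundance model.

    ``abundance_model`` is ``"uniform"`` (the equal-tissue mock
    community) or ``"lognormal"`` (skewed; produces singletons at
    realistic rates).  Species listed in ``dropout_species`` are removed
    from the pool, mimicking amplification failure.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not templates:
        raise ValueError("templates must be nonempty")
    rng = np.random.default_rng(seed)
    species = [s for s in sorted(templates) if s not in set(dropout_species)]
    if not species:
        raise ValueError("all species dropped out")
    if abundance_model == "uniform":
        weights = np.full(len(species), 1.0 / len(species))
    elif abundance_model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma,
                            size=len(species))
        weights = raw / raw.sum()
    else:
        raise ValueError(f"unknown abundance model {abundance_model!r}")
    reads: list[Read] = []
    truth: dict[str, GroundTruthEntry] = {}
    for i in range(n_reads):
        read_id = f"read_{i + 1:06d}"
        sp_idx = int(rng.choice(len(species), p=weights))
        sp = species[sp_idx]
        copies = templates[sp]
        copy_index = int(rng.integers(len(copies)))
        template = copies[copy_index]
        is_chimera = False
        parents = None
        if err.chimera_rate > 0 and rng.random() < err.chimera_rate:
            other_idx = int(rng.choice(len(species), p=weights))
            if other_idx != sp_idx:
                other = species[other_idx]
                other_template = templates[other][
                    int(rng.integers(len(templates[other])))]
                frac = rng.uniform(0.2, 0.8)
                template = (template[:int(frac * len(template))]
                            + other_template[int(frac * len(other_template)):])
                is_chimera = True
                parents = (sp, other)
        seq, n_errors = _apply_errors(rng, template, err)
        seq = _realize_primer(rng, primer) + seq
        reads.append(Read(read_id, seq, _qualities(rng, len(seq), err)))
        truth[read_id] = GroundTruthEntry(sp, copy_index, is_chimera,
                                          parents, n_errors)
    return reads, truth


def write_ground_truth_tsv(truth: dict[str, GroundTruthEntry],
                           path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tspecies\tcopy_index\tis_chimera\t"
                     "chimera_parents\tn_errors\n")
        for read_id in sorted(truth):
            e = truth[read_id]
            parents = ",".join(e.chimera_parents) if e.chimera_parents else "-"
            handle.write(f"{read_id}\t{e.species}\t{e.copy_index}\t"
                         f"{int(e.is_chimera)}\t{parents}\t"
                         f"{e.n_errors_injected}\n")


def read_ground_truth_tsv(path: str | Path) -> dict[str, GroundTruthEntry]:
    truth = {}
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            read_id, sp, copy_idx, chim, parents, n_err = (
                line.rstrip("\n").split("\t"))
            truth[read_id] = GroundTruthEntry(
                sp, int(copy_idx), chim == "1",
                tuple(parents.split(",")) if parents != "-" else None,
                int(n_err))
    return truth


# ---------------------------------------------------------------------------
# curated fixtures exercised across the test suite

@dataclass(frozen=True)
class FixtureData:
    name: str
    uniques: tuple[UniqueSequence, ...] = ()
    reads: tuple[Read, ...] = ()
    references: tuple[ReferenceRecord, ...] = ()
    ground_truth: dict[str, GroundTruthEntry] = field(default_factory=dict)
    note: str = ""


def _substitute_at(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    """Substitute exactly n distinct positions (a fixed-divergence variant)."""
    positions = rng.choice(len(seq), size=n_sites, replace=False)
    seq_list = list(seq)
    for pos in positions:
        choices = [b for b in _BASES if b != seq_list[pos]]
        seq_list[pos] = choices[int(rng.integers(3))]
    return "".join(seq_list)


def fixture_suite(seed: int = 7) -> dict[str, FixtureData]:
    """Small deterministic datasets targeting specific failure modes.

    * ``length_variant_pair`` — a 440-nt sequence and its 400-nt prefix;
      terminal-gap handling decides whether they share an OTU at 3%.
    * ``close_species_pair`` — two species 1% apart (undersplitting at
      a 3% threshold, split at 1%).
    * ``divergent_copies`` — one species with two gene copies 10% apart
      (oversplitting at 3%).
    * ``lognormal_community`` — a small skewed-abundance community whose
      dereplicated output contains singletons.
    """
    rng = np.random.default_rng(seed)
    fixtures: dict[str, FixtureData] = {}

    full = _random_sequence(rng, 440)
    prefix = full[:400]
    fixtures["length_variant_pair"] = FixtureData(
        name="length_variant_pair",
        uniques=(UniqueSequence(full, 5, [f"lv_{i}" for i in range(5)]),
                 UniqueSequence(prefix, 3, [f"lp_{i}" for i in range(3)])),
        note="prefix pair: 40 terminal gap columns in any optimal alignment",
    )

    base = _random_sequence(rng, 400)
    close = _substitute_at(rng, base, 4)  # 1% divergence
    fixtures["close_species_pair"] = FixtureData(
        name="close_species_pair",
        uniques=(UniqueSequence(base, 5, [f"cs_a{i}" for i in range(5)]),
                 UniqueSequence(close, 4, [f"cs_b{i}" for i in range(4)])),
        references=(ReferenceRecord("species_A", base),
                    ReferenceRecord("species_B", close)),
        ground_truth={
            **{f"cs_a{i}": GroundTruthEntry("species_A", 0, False, None, 0)
               for i in range(5)},
            **{f"cs_b{i}": GroundTruthEntry("species_B", 0, False, None, 0)
               for i in range(4)},
        },
        note="two species 1% apart: one OTU at 3%, two at 1%",
    )

    template = _random_sequence(rng, 420)
    far_copy = _substitute_at(rng, template, 42)  # 10% divergence
    fixtures["divergent_copies"] = FixtureData(
        name="divergent_copies",
        uniques=(UniqueSequence(template, 6, [f"dc_a{i}" for i in range(6)]),
                 UniqueSequence(far_copy, 2, [f"dc_b{i}" for i in range(2)])),
        references=(ReferenceRecord("species_C", template),),
        ground_truth={
            **{f"dc_a{i}": GroundTruthEntry("species_C", 0, False, None, 0)
               for i in range(6)},
            **{f"dc_b{i}": GroundTruthEntry("species_C", 1, False, None, 0)
               for i in range(2)},
        },
        note="two gene copies 10% apart oversplit one species at 3%",
    )

    spec = CommunitySpec(n_species=6, length_range=(420, 520),
                         copies_per_species=(1, 1), seed=seed)
    refs, templates = generate_references(spec)
    reads, truth = simulate_reads(
        templates, n_reads=300,
        err=ErrorModel(sub_rate=0.001, indel_rate=0.0,
                       homopolymer_slip_prob=0.0, chimera_rate=0.0),
        seed=seed, abundance_model="lognormal")
    fixtures["lognormal_community"] = FixtureData(
        name="lognormal_community",
        reads=tuple(reads),
        references=tuple(refs),
        ground_truth=truth,
        note="skewed abundances with sparse errors yield singleton uniques",
    )
    return fixtures
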