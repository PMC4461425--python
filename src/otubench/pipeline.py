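"""Config-driven orchestration: filter -> dereplicate -> cluster -> classify.

``run_workflow`` executes one configuration end to end and leaves every
intermediate artifact plus a JSON-lines log on disk.  ``compare_workflows``
runs the factorial grid (filter regime x singleton policy x algorithm x
identity definition) sharing the filtered/dereplicated datasets and the
global alignment cache across combinations.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .amplicon_io import Read, read_aligned_fasta, read_fastq, write_fastq
from .clustering import (
    AcceptMode,
    ClusterAlgorithm,
    ClusterConfig,
    Linkage,
    OTU,
    cluster,
    write_membership_tsv,
    write_otu_fasta,
)
from .dereplication import dereplicate, remove_singletons, write_unique_fasta
from .errors import CapacityError, OtubenchError
from .evaluation import (
    Classification,
    EvaluationSummary,
    ReferenceRecord,
    classify_otus,
    load_references,
    summarize,
    write_classification_tsv,
)
from .pairwise_identity import (
    DEFAULT_SCORING,
    GapDefinition,
    IdentityConfig,
    ScoringScheme,
    TerminalPolicy,
)
from .read_filtering import FilterParams, FilterRegime, FilterReport, apply_filter


@dataclass(frozen=True)
class WorkflowConfig:
    """One workflow: filtering, singleton policy, clustering, classification."""

    filter: FilterParams = field(
        default_factory=lambda: FilterParams.stringent())
    keep_singletons: bool = False
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    min_identity: float = 0.90
    min_overlap: int = 200
    reads_path: str | None = None
    reference_path: str | None = None
    msa_path: str | None = None
    out_dir: str | None = None
    seed: int = 0

    # -- lossless round-trip through plain dictionaries / YAML ------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"]["regime"] = self.filter.regime.value
        c = d["cluster"]
        c["algorithm"] = self.cluster.algorithm.value
        c["linkage"] = self.cluster.linkage.value
        c["accept_mode"] = self.cluster.accept_mode.value
        c["identity_cfg"] = {
            "definition": self.cluster.identity_cfg.definition.value,
            "terminal_policy": self.cluster.identity_cfg.terminal_policy.value,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        d = dict(d)
        f = dict(d.pop("filter"))
        f["regime"] = FilterRegime(f["regime"])
        c = dict(d.pop("cluster"))
        ic = c.pop("identity_cfg")
        c["identity_cfg"] = IdentityConfig(
            definition=GapDefinition(ic["definition"]),
            terminal_policy=TerminalPolicy(ic["terminal_policy"]))
        c["algorithm"] = ClusterAlgorithm(c["algorithm"])
        c["linkage"] = Linkage(c["linkage"])
        c["accept_mode"] = AcceptMode(c["accept_mode"])
        return cls(filter=FilterParams(**f), cluster=ClusterConfig(**c), **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def build_msa_mafft(sequences: Sequence[str]):
    """Multiple-align sequences with MAFFT (default settings, 1 thread).

    Returns AlignedSeqRecord rows in input order with ids ``u<i>``, or
    raises ``RuntimeError`` when the mafft binary is unavailable.
    """
    from .amplicon_io import AlignedSeqRecord  # local import to avoid cycle

    if not mafft_available():
        raise RuntimeError("mafft binary not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "in.fasta"
        with open(in_path, "w") as handle:
            for i, seq in enumerate(sequences):
                handle.write(f">u{i}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--thread", "1", str(in_path)],
            capture_output=True, text=True, check=True)
    rows: list[AlignedSeqRecord] = []
    seq_id = None
    chunks: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if seq_id is not None:
                rows.append(AlignedSeqRecord(seq_id, "".join(chunks).upper()))
            seq_id = line[1:].strip()
            chunks = []
        else:
            chunks.append(line.strip())
    if seq_id is not None:
        rows.append(AlignedSeqRecord(seq_id, "".join(chunks).upper()))
    order = sorted(range(len(rows)), key=lambda k: int(rows[k].seq_id[1:]))
    return [rows[k] for k in order]


def _msa_for(uniques, ccfg: ClusterConfig, use_mafft: bool):
    """MSA rows for hierarchical clustering, or None to fall back to
    all-pairs global alignment distances."""
    if (not use_mafft or ccfg.algorithm is not ClusterAlgorithm.HIERARCHICAL
            or len(uniques) < 3 or len(uniques) > ccfg.max_matrix_size
            or not mafft_available()):
        return None
    return build_msa_mafft([u.sequence for u in uniques])


@dataclass
class WorkflowResult:
    filter_report: FilterReport
    n_uniques: int
    n_uniques_after_policy: int
    otus: list[OTU]
    classifications: list[Classification] | None
    summary: EvaluationSummary | None
    warning: str | None = None

    @property
    def n_otus(self) -> int:
        return len(self.otus)


def execute_workflow(reads: Sequence[Read],
                     references: Sequence[ReferenceRecord] | None,
                     cfg: WorkflowConfig,
                     msa=None,
                     scoring: ScoringScheme = DEFAULT_SCORING,
                     use_mafft: bool = True,
                     ) -> WorkflowResult:
    """Run the fixed stage order on in-memory data.

    Classification is skipped when no reference set is given (the
    natural-community mode: only OTU counts are meaningful).  For
    hierarchical clustering without a supplied MSA an alignment is built
    with MAFFT when the binary is available (``use_mafft``), otherwise
    distances come from all-pairs global alignment.
    """
    kept, report = apply_filter(reads, cfg.filter)
    uniques = dereplicate(kept)
    n_uniques = len(uniques)
    if not cfg.keep_singletons:
        uniques = remove_singletons(uniques)
    if not uniques:
        return WorkflowResult(report, n_uniques, 0, [], None, None,
                              warning="no sequences survived filtering")
    if msa is None:
        msa = _msa_for(uniques, cfg.cluster, use_mafft)
    otus = cluster(uniques, cfg.cluster, msa=msa, scoring=scoring)
    classifications = None
    summary = None
    if references:
        classifications = classify_otus(
            otus, references, min_identity=cfg.min_identity,
            min_overlap=cfg.min_overlap, scoring=scoring)
        summary = summarize(classifications, references, len(otus))
    return WorkflowResult(report, n_uniques, len(uniques), otus,
                          classifications, summary)


def _summary_payload(result: WorkflowResult) -> dict:
    payload: dict = {
        "n_otus": result.n_otus,
        "n_uniques": result.n_uniques,
        "n_uniques_after_singleton_policy": result.n_uniques_after_policy,
        "filter": result.filter_report.as_dict(),
    }
    if result.summary is not None:
        payload["evaluation"] = asdict(result.summary)
    if result.warning:
        payload["warning"] = result.warning
    return payload


def run_workflow(cfg: WorkflowConfig,
                 scoring: ScoringScheme = DEFAULT_SCORING) -> WorkflowResult:
    """Execute a configuration from disk paths and write all artifacts."""
    if cfg.reads_path is None or cfg.out_dir is None:
        raise ValueError("run_workflow requires reads_path and out_dir")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    log_entries: list[dict] = []

    def log(stage: str, **fields) -> None:
        log_entries.append({"stage": stage, **fields})

    try:
        reads = read_fastq(cfg.reads_path)
        log("read_fastq", n_reads=len(reads))
        references = (load_references(cfg.reference_path)
                      if cfg.reference_path else None)
        msa = read_aligned_fasta(cfg.msa_path) if cfg.msa_path else None
        kept, report = apply_filter(reads, cfg.filter)
        log("filter", **report.as_dict())
        write_fastq(kept, out / "kept.fastq")
        uniques = dereplicate(kept)
        log("dereplicate", n_uniques=len(uniques))
        n_uniques = len(uniques)
        if not cfg.keep_singletons:
            uniques = remove_singletons(uniques)
            log("remove_singletons", n_uniques=len(uniques))
        write_unique_fasta(uniques, out / "uniques.fasta")
        if not uniques:
            result = WorkflowResult(report, n_uniques, 0, [], None, None,
                                    warning="no sequences survived filtering")
        else:
            otus = cluster(uniques, cfg.cluster, msa=msa, scoring=scoring)
            log("cluster", n_otus=len(otus))
            classifications = None
            summary = None
            if references:
                classifications = classify_otus(
                    otus, references, min_identity=cfg.min_identity,
                    min_overlap=cfg.min_overlap, scoring=scoring)
                summary = summarize(classifications, references, len(otus))
                log("classify",
                    n_matched=summary.n_matched_otus,
                    n_species_detected=summary.n_species_detected)
            result = WorkflowResult(report, n_uniques, len(uniques), otus,
                                    classifications, summary)
        write_otu_fasta(result.otus, out / "otus.fasta")
        write_membership_tsv(result.otus, out / "membership.tsv")
        if result.classifications is not None:
            write_classification_tsv(result.classifications,
                                     out / "classification.tsv")
        with open(out / "summary.json", "w") as handle:
            json.dump(_summary_payload(result), handle, indent=2,
                      sort_keys=True)
            handle.write("\n")
        return result
    except OtubenchError as exc:
        stage = log_entries[-1]["stage"] if log_entries else "setup"
        raise OtubenchError(f"workflow failed after stage "
                            f"{stage!r}: {exc}") from exc
    finally:
        with open(log_path, "w") as handle:
            for entry in log_entries:
                handle.write(json.dumps(entry, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# the factorial workflow grid

GRID_COLUMNS = ["filter", "singletons", "algorithm", "definition",
                "n_otus", "n_matched_otus", "n_species_detected",
                "precision", "status", "cell"]


def compare_workflows(
        reads: Sequence[Read],
        references: Sequence[ReferenceRecord] | None,
        regimes: Sequence[FilterRegime] = (FilterRegime.STRINGENT,
                                           FilterRegime.RELAXED),
        singleton_policies: Sequence[bool] = (False, True),
        algorithms: Sequence[ClusterAlgorithm] = (
            ClusterAlgorithm.GREEDY, ClusterAlgorithm.HIERARCHICAL),
        definitions: Sequence[GapDefinition] = (
            GapDefinition.NO_GAPS, GapDefinition.ONE_GAP,
            GapDefinition.EACH_GAP),
        divergence_threshold: float = 0.03,
        terminal_policy: TerminalPolicy = TerminalPolicy.COUNT,
        max_matrix_size: int = 20000,
        min_identity: float = 0.90,
        min_overlap: int = 200,
        filter_overrides: dict | None = None,
        scoring: ScoringScheme = DEFAULT_SCORING,
        use_mafft: bool = True,
) -> pd.DataFrame:
    """Run every combination of the grid on shared inputs.

    Per-combination failures (notably the hierarchical capacity guard)
    are recorded in the ``status`` column and do not abort the grid.
    """
    overrides = filter_overrides or {}
    datasets: dict[tuple, list] = {}
    for regime in regimes:
        params = (FilterParams.stringent(**overrides)
                  if regime is FilterRegime.STRINGENT
                  else FilterParams.relaxed(**overrides))
        kept, _ = apply_filter(reads, params)
        uniques = dereplicate(kept)
        for keep_singletons in singleton_policies:
            datasets[(regime, keep_singletons)] = (
                uniques if keep_singletons else remove_singletons(uniques))

    rows = []
    msa_cache: dict[tuple, object] = {}
    for regime in regimes:
        for keep_singletons in singleton_policies:
            uniques = datasets[(regime, keep_singletons)]
            for algorithm in algorithms:
                for definition in definitions:
                    ccfg = ClusterConfig(
                        algorithm=algorithm,
                        divergence_threshold=divergence_threshold,
                        identity_cfg=IdentityConfig(definition,
                                                    terminal_policy),
                        max_matrix_size=max_matrix_size)
                    row = {
                        "filter": regime.value,
                        "singletons": ("included" if keep_singletons
                                       else "removed"),
                        "algorithm": algorithm.value,
                        "definition": definition.value,
                        "n_otus": None, "n_matched_otus": None,
                        "n_species_detected": None, "precision": None,
                        "status": "ok", "cell": "-",
                    }
                    msa = None
                    if algorithm is ClusterAlgorithm.HIERARCHICAL:
                        key = (regime, keep_singletons)
                        if key not in msa_cache:
                            msa_cache[key] = _msa_for(uniques, ccfg, use_mafft)
                        msa = msa_cache[key]
                    try:
                        otus = cluster(uniques, ccfg, msa=msa,
                                       scoring=scoring)
                    except CapacityError:
                        row["status"] = "infeasible"
                        rows.append(row)
                        continue
                    except OtubenchError as exc:
                        row["status"] = f"error: {exc}"
                        rows.append(row)
                        continue
                    row["n_otus"] = len(otus)
                    if references and otus:
                        classifications = classify_otus(
                            otus, references, min_identity=min_identity,
                            min_overlap=min_overlap, scoring=scoring)
                        summary = summarize(classifications, references,
                                            len(otus))
                        row["n_matched_otus"] = summary.n_matched_otus
                        row["n_species_detected"] = summary.n_species_detected
                        row["precision"] = summary.precision
                        row["cell"] = (f"{summary.n_otus} "
                                       f"({summary.n_matched_otus}) "
                                       f"{summary.n_species_detected}")
                    else:
                        row["cell"] = str(len(otus))
                    rows.append(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def grid_table(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the grid into a table: rows = identity definition,
    columns = filter x singletons x algorithm, cells = 'total (matched)
    detected' (or 'infeasible')."""
    view = df.copy()
    view.loc[view["status"] != "ok", "cell"] = view["status"]
    return view.pivot_table(
        index="definition",
        columns=["filter", "singletons", "algorithm"],
        values="cell", aggfunc="first", sort=False)
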