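# otubench

Benchmarking OTU-clustering workflows for length-variable amplicons
(18S-V4-like markers sequenced with 454-style long reads).

The package implements an end-to-end, fully testable version of a classic
metabarcoding workflow comparison:

* **read filtering** — a *stringent* regime (primer match, <400 bp removed,
  trim to 400 bp, no Ns, expected error ≤ 0.5) and a *relaxed* regime
  (primer match, length window 250–600 bp, no Ns, mean quality ≥ 20);
* **dereplication** with an explicit singleton policy (include/remove
  abundance-1 unique sequences);
* **pairwise identity** under three gap definitions — *no gaps* (gap columns
  excluded), *one gap* (each gap run is one difference), *each gap* (each
  gap column is one difference) — with a configurable terminal-gap policy
  (count terminal runs as differences, or treat them as missing data);
* **clustering** at a divergence threshold (default 3%) by a greedy
  abundance-ordered centroid algorithm (UCLUST-style) or hierarchical
  agglomeration over a full distance matrix (mothur-style; average,
  furthest or nearest linkage), optionally from a multiple sequence
  alignment (built with MAFFT when available);
* **evaluation** against a reference database: best-hit classification
  (≥ 90% identity over ≥ 200 aligned nt), precision (species recovered /
  OTUs produced), species detection, and a ground-truth audit of
  oversplitting/undersplitting;
* **a synthetic mock community** generator: length-variable species
  templates, intragenomic rRNA copies (including slippage-style block
  indels), substitution/indel/homopolymer-slip read errors, chimeras, and
  per-read ground-truth labels.

The `pipeline` module orchestrates filter → dereplicate → cluster →
classify from a YAML config and runs the full factorial grid
(filter × singleton policy × algorithm × identity definition).

## CLI

```sh
# simulate a mock community (references, reads, ground truth)
otubench simulate --n-species 43 --n-reads 5000 --seed 1 --out sim/

# filter reads under one regime
otubench filter --regime stringent --in sim/reads.fastq \
    --out kept.fastq --report report.json

# run one workflow from a YAML config
otubench run -c workflow.yaml

# run the factorial workflow grid
otubench grid -c grid.yaml
```

A workflow YAML is produced by `WorkflowConfig.to_yaml()`; every
threshold (trim length, length window, expected error, mean quality,
divergence threshold, classification identity/overlap) is a named key
with the benchmark defaults.

## Notes on alignment scoring

Pairwise alignments are optimal global (Needleman–Wunsch) alignments
with affine gap costs (match +1, mismatch −2, gap open −10, extend −1).
Terminal gap runs are scored at a cheap flat rate (−1 per column) rather
than free: completely free end gaps make the optimum for unrelated
sequences degenerate to a single-column overlap, which would assign
near-perfect *no gaps* identity to arbitrary pairs. The cheap-but-nonzero
rate keeps maximal-overlap alignments optimal while still producing the
explicit terminal gap runs whose treatment the identity definitions
disagree about. `ScoringScheme.free_end_gaps()` and
`ScoringScheme.full_global()` expose the alternatives.
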