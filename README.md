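# cobind

Multi-factor ChIP-seq co-binding analysis on an accessible-chromatin null,
with everything needed to exercise it offline on synthetic data:

- **Interval core** — 0-based half-open intervals, 1-based-inclusive
  coordinate-string parsing, merging, BED/narrowPeak/gene-table/FASTA I/O.
- **Overlap statistics** — center-distance peak overlap (default < 150 bp),
  binomial significance against an accessible-chromatin null
  (`N_AB ~ Binom(N_A, p_B)`, `p_B = window·N_B / accessible_size`),
  multi-factor regulatory-hotspot calling (1 kb clique rule), target-set
  ratios, core-target intersection, and score-by-co-binding partitions.
  p-values are computed in log space, so −log10 p stays exact far below
  float underflow (the 10⁻³⁰⁰…10⁻¹⁵⁰⁰ regime).
- **Motif statistics** — PWM scanning (log-odds vs uniform background, both
  strands, exact DP p-value→threshold mapping), matched random peak sets
  that preserve each peak's signed distance to its nearest TSS exactly while
  permuting gene assignments, and the matched-background binomial enrichment
  (plus a dimensionally conventional `per_bp_trials` variant).
- **Target mapping** — regulatory domains (±500 kb flank, single-nearest-TSS,
  or basal 5 kb/1 kb + extension), center-based peak→gene assignment, and
  background-normalized region enrichment
  (`N_Ax ~ Binom(N_A, p_x·r_Ax)` with `r_Ax` averaged over random gene lists).
- **Expression analysis** — RPKM and exonic-ratio TPM, differential sets at
  fold > 3 / TPM > 5 / p < 0.05 (Welch on log2(TPM+1)), threshold-only
  population lists (TPM > 10, fold > 2), and category-fraction tables.
- **Rearrangement** — inversion+deletion position maps (bijective on
  surviving bases), feature re-mapping with split/drop reporting, and
  boundary-aware enhancer–promoter contact prediction (blocking is
  topological, never distance-based).
- **Synthetic data** — seeded generators for genomes, annotations,
  accessible chromatin, co-bound peaks around shared anchors, planted motif
  instances, and multi-population expression tables, each with ground-truth
  tables.

## CLI

```sh
cobind run-all --config configs/demo.yaml --seed 0 --out demo_run
```

runs simulate → overlap/hotspots → motif → targets/enrichment → expression →
rearrangement and writes TSV reports (each with a parameter header) plus a
`truth/` directory. Re-running with the same config is byte-identical.

Individual stages: `cobind simulate | overlap | hotspots | motif | targets |
enrich | expression | rearrange` (see `cobind <cmd> --help`). Exit codes:
0 ok, 1 user error, 2 internal error.

Example (on a simulated dataset):

```sh
cobind simulate --seed 4 --out sim
cobind overlap --peaks-a sim/peaks_factorA.bed --peaks-b sim/peaks_factorB.bed \
    --atac sim/accessible.bed --chrom-sizes sim/chrom.sizes
```

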