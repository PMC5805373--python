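"""Synthetic data generators: genomes, gene annotations, accessible
chromatin, co-bound peak sets around shared anchors, planted motif
instances, and expression tables with planted enriched gene sets.

Everything is a pure function of (spec, seed); ground-truth tables record
every planted signal so downstream confusion matrices never need to peek at
generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeModel, GenomicInterval, PeakSet
from .genes import GeneAnnotation, GeneRecord
from .overlap import AccessibleChromatin

__all__ = [
    "CobindingSpec",
    "ExpressionSpec",
    "simulate_genome",
    "simulate_accessible",
    "simulate_peaks",
    "plant_motifs",
    "simulate_expression",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CobindingSpec:
    """Plan for multi-factor peak simulation around shared anchors."""

    factors: tuple[str, ...]
    n_anchors: int
    n_specific: dict[str, int]  # factor -> count of factor-private peaks
    jitter_sd: float = 50.0
    width_min: int = 100
    width_max: int = 400
    cobinding: dict[str, float] = field(default_factory=dict)  # factor -> P(bind anchor)
    accessible_fraction: float = 0.1
    accessible_region_bp: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if not (0 < self.width_min <= self.width_max):
            raise ValueError("need 0 < width_min <= width_max")
        if not (0.0 < self.accessible_fraction <= 1.0):
            raise ValueError("accessible_fraction must be in (0, 1]")
        for f, p in self.cobinding.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"cobinding probability for {f!r} outside [0,1]")
        if self.accessible_region_bp < 2 * self.width_max:
            raise ValueError("accessible regions must fit the widest peak twice over")

    def binding_prob(self, factor: str) -> float:
        return self.cobinding.get(factor, 1.0)


@dataclass(frozen=True)
class ExpressionSpec:
    """Plan for a multi-population expression table with planted effects."""

    populations: tuple[str, ...]
    n_genes: int
    baseline_log_mean: float = 2.0  # natural-log scale of the log-normal TPM baseline
    baseline_log_sd: float = 1.0
    planted: dict[str, tuple[int, float]] = field(default_factory=dict)  # pop -> (n, fold)
    replicates: int = 3
    dispersion: float = 0.3  # sd of log-normal replicate noise
    total_reads: float = 10_000_000.0
    exonic_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per population")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for pop, (n, fold) in self.planted.items():
            if pop not in self.populations:
                raise ValueError(f"planted population {pop!r} not in populations")
            if fold <= 1.0:
                raise ValueError("planted fold-effect must exceed 1")
            if n < 0:
                raise ValueError("planted gene count must be >= 0")


def simulate_genome(
    n_chroms: int,
    chrom_len: int,
    n_genes: int,
    seed: int | np.random.Generator,
    with_sequence: bool = True,
) -> tuple[GenomeModel, GeneAnnotation, dict[str, str]]:
    """Uniform-random genome: equal-size chromosomes, uniformly placed TSS
    with random strand, i.i.d. uniform ACGT sequence.  Deterministic per seed.
    """
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10 kb")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if n_genes > n_chroms * chrom_len // 1_000:
        raise ValueError("gene placement overconstrained: denser than 1 gene/kb")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    genome = GenomeModel(chrom_sizes)

    chrom_of = rng.integers(0, n_chroms, size=n_genes)
    genes: list[GeneRecord] = []
    used: dict[int, set[int]] = {c: set() for c in range(n_chroms)}
    for g in range(n_genes):
        c = int(chrom_of[g])
        while True:
            tss = int(rng.integers(0, chrom_len))
            if tss not in used[c]:
                used[c].add(tss)
                break
        strand = "+" if rng.random() < 0.5 else "-"
        exonic_bp = int(rng.integers(500, 5_001))
        genes.append(GeneRecord(f"gene{g + 1:05d}", f"chr{c + 1}", strand, tss, exonic_bp))
    annotation = GeneAnnotation(genes)

    sequences: dict[str, str] = {}
    if with_sequence:
        for chrom in genome.chroms:
            codes = rng.integers(0, 4, size=chrom_len)
            sequences[chrom] = "".join(_BASES[codes])
    return genome, annotation, sequences


def simulate_accessible(
    genome: GenomeModel,
    fraction: float,
    region_bp: int,
    rng: np.random.Generator,
) -> AccessibleChromatin:
    """Disjoint accessible windows of fixed width covering ~``fraction`` of
    the genome, placed on a jittered grid so regions never touch."""
    regions: list[GenomicInterval] = []
    for chrom, size in genome.chrom_sizes.items():
        n_regions = max(1, int(round(size * fraction / region_bp)))
        stride = size // n_regions
        if stride < region_bp + 2:
            raise ValueError("accessible fraction too high for the region width")
        for i in range(n_regions):
            slack = stride - region_bp - 1
            offset = int(rng.integers(0, max(1, slack)))
            start = i * stride + offset
            regions.append(GenomicInterval(chrom, start, start + region_bp))
    total = sum(len(r) for r in regions)
    return AccessibleChromatin(tuple(regions), total)


def _place_in_region(
    region: GenomicInterval, center: int, width: int
) -> GenomicInterval:
    """Peak of ``width`` bp around ``center``, clamped fully inside ``region``."""
    start = center - width // 2
    start = max(region.start, min(start, region.end - width))
    return GenomicInterval(region.chrom, start, start + width)


def simulate_peaks(
    spec: CobindingSpec,
    genome: GenomeModel,
    max_retries: int = 50,
) -> tuple[dict[str, PeakSet], pd.DataFrame, AccessibleChromatin]:
    """Simulate per-factor peak sets inside accessible chromatin.

    Anchors (shared co-binding sites) are drawn inside accessible regions at
    least ``2 * width_max`` apart; each factor binds each anchor with its
    cobinding probability, centering its peak within Gaussian jitter of the
    anchor.  Factor-specific peaks land uniformly in accessible regions.

    Returns (peak sets, ground-truth table, accessible chromatin).  Truth
    columns: factor, peak_index, origin ('anchor' or 'specific'), anchor_id,
    anchor_pos, center, score.
    """
    rng = np.random.default_rng(spec.seed)
    accessible = simulate_accessible(
        genome, spec.accessible_fraction, spec.accessible_region_bp, rng
    )
    regions = list(accessible.regions)

    # anchors: one region can host at most one anchor, which enforces the
    # minimum separation as long as region_bp >= 2*width_max
    if spec.n_anchors > len(regions):
        raise ValueError(
            f"cannot place {spec.n_anchors} anchors in {len(regions)} accessible regions"
        )
    anchor_regions = rng.choice(len(regions), size=spec.n_anchors, replace=False)
    anchors: list[tuple[int, GenomicInterval, int]] = []
    for aid, ri in enumerate(sorted(int(i) for i in anchor_regions)):
        region = regions[ri]
        margin = spec.width_max // 2 + int(4 * spec.jitter_sd)
        lo = region.start + min(margin, len(region) // 3)
        hi = region.end - min(margin, len(region) // 3)
        pos = int(rng.integers(lo, max(lo + 1, hi)))
        anchors.append((aid, region, pos))

    peak_sets: dict[str, PeakSet] = {}
    truth_rows: list[dict] = []
    for factor in spec.factors:
        intervals: list[GenomicInterval] = []
        rows: list[dict] = []
        prob = spec.binding_prob(factor)
        for aid, region, pos in anchors:
            if rng.random() >= prob:
                continue
            for _ in range(max_retries):
                jitter = int(round(rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd else 0
                c = pos + jitter
                if region.start <= c < region.end:
                    break
            else:
                c = pos
            width = int(rng.integers(spec.width_min, spec.width_max + 1))
            iv = _place_in_region(region, c, width)
            rows.append(
                {
                    "factor": factor,
                    "origin": "anchor",
                    "anchor_id": aid,
                    "anchor_pos": pos,
                    "chrom": iv.chrom,
                    "center": iv.center,
                }
            )
            intervals.append(iv)
        n_spec = spec.n_specific.get(factor, 0)
        for _ in range(n_spec):
            region = regions[int(rng.integers(0, len(regions)))]
            width = int(rng.integers(spec.width_min, spec.width_max + 1))
            c = int(rng.integers(region.start + width // 2, region.end - width // 2 + 1))
            iv = _place_in_region(region, c, width)
            rows.append(
                {
                    "factor": factor,
                    "origin": "specific",
                    "anchor_id": -1,
                    "anchor_pos": -1,
                    "chrom": iv.chrom,
                    "center": iv.center,
                }
            )
            intervals.append(iv)
        # score: noisy base signal plus a bonus per co-binding anchor factor
        order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
        scored = []
        for rank, i in enumerate(order):
            row = rows[i]
            base = float(rng.gamma(4.0, 2.0))
            bonus = 2.0 if row["origin"] == "anchor" else 0.0
            iv = intervals[i]
            scored.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, base + bonus))
            row["score"] = base + bonus
            row["peak_index"] = rank
        peak_sets[factor] = PeakSet(factor, scored)
        truth_rows.extend(rows[i] for i in order)

    truth = pd.DataFrame(
        truth_rows,
        columns=["factor", "peak_index", "origin", "anchor_id", "anchor_pos", "chrom", "center", "score"],
    )
    return peak_sets, truth, accessible


def plant_motifs(
    sequences: dict[str, str],
    peaks: PeakSet,
    consensus: str,
    plant_prob: float,
    positional_sd: float,
    seed: int | np.random.Generator,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write ``consensus`` into the sequence near peak centers.

    Each peak receives one instance with probability ``plant_prob``, centered
    at the peak center plus Gaussian offset, on a random strand.  Returns the
    modified sequences and a ground-truth table (one row per peak, planted or
    skipped).
    """
    if not (0.0 <= plant_prob <= 1.0):
        raise ValueError("plant_prob must be in [0,1]")
    consensus = consensus.upper()
    if set(consensus) - set("ACGT"):
        raise ValueError("consensus must be over ACGT")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    editable = {chrom: list(seq) for chrom, seq in sequences.items()}
    L = len(consensus)
    rows: list[dict] = []
    for i, iv in enumerate(peaks):
        planted = rng.random() < plant_prob
        status = "planted" if planted else "unplanted"
        position = -1
        strand = "."
        if planted:
            if L > len(iv):
                import warnings

                warnings.warn(f"consensus ({L} bp) longer than peak {i}; skipped")
                status = "skipped_too_long"
            else:
                offset = int(round(rng.normal(0.0, positional_sd))) if positional_sd else 0
                start = iv.center + offset - L // 2
                start = max(0, min(start, len(sequences[iv.chrom]) - L))
                strand = "+" if rng.random() < 0.5 else "-"
                inst = consensus if strand == "+" else consensus.translate(_COMPLEMENT)[::-1]
                editable[iv.chrom][start : start + L] = list(inst)
                position = start
        rows.append(
            {
                "peak_index": i,
                "chrom": iv.chrom,
                "peak_center": iv.center,
                "status": status,
                "position": position,
                "strand": strand,
            }
        )
    out = {chrom: "".join(chars) for chrom, chars in editable.items()}
    truth = pd.DataFrame(rows)
    # later plants can clobber earlier overlapping ones; record the casualty
    for idx, row in truth.iterrows():
        if row["status"] != "planted":
            continue
        written = out[row["chrom"]][row["position"] : row["position"] + L]
        expected = consensus if row["strand"] == "+" else consensus.translate(_COMPLEMENT)[::-1]
        if written != expected:
            truth.loc[idx, "status"] = "overwritten"
    return out, truth


def simulate_expression(
    spec: ExpressionSpec,
    genes: GeneAnnotation,
    seed: int | np.random.Generator,
) -> tuple["pd.DataFrame", dict, pd.DataFrame]:
    """Simulate a counts table with planted population-enriched gene sets.

    Per-gene baseline TPM is log-normal; planted genes get their population's
    fold-effect multiplied in.  Replicate TPMs carry log-normal noise of sd
    ``dispersion``; counts are back-computed so that the TPM convention
    recovers the noisy values exactly.

    Returns (counts, sample metadata dict, truth table).  The metadata dict
    holds populations / total_reads / exonic_ratios keyed by sample name.
    """
    if len(genes) < spec.n_genes:
        raise ValueError("annotation has fewer genes than spec.n_genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in list(genes)[: spec.n_genes]]
    exonic = np.array([genes[g].exonic_bp for g in gene_ids], dtype=float)

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, size=spec.n_genes)
    effect = np.ones((spec.n_genes, len(spec.populations)))
    truth_rows: list[dict] = []
    available = np.arange(spec.n_genes)
    rng.shuffle(available)
    cursor = 0
    for p_i, pop in enumerate(spec.populations):
        if pop not in spec.planted:
            continue
        n, fold = spec.planted[pop]
        chosen = available[cursor : cursor + n]
        cursor += n
        if len(chosen) < n:
            raise ValueError("not enough genes to plant all enriched sets disjointly")
        effect[chosen, p_i] *= fold
        for g in chosen:
            truth_rows.append({"gene_id": gene_ids[int(g)], "population": pop, "fold": fold})

    samples: list[str] = []
    populations: dict[str, str] = {}
    tpm_cols = {}
    for p_i, pop in enumerate(spec.populations):
        for r in range(spec.replicates):
            name = f"{pop}_rep{r + 1}"
            samples.append(name)
            populations[name] = pop
            noise = (
                rng.lognormal(0.0, spec.dispersion, size=spec.n_genes)
                if spec.dispersion > 0
                else np.ones(spec.n_genes)
            )
            tpm_cols[name] = baseline * effect[:, p_i] * noise

    tpm = pd.DataFrame(tpm_cols, index=gene_ids)
    # invert the TPM convention so compute_tpm round-trips exactly:
    # count = TPM * ratio * kb * millions
    kb = exonic / 1_000.0
    millions = spec.total_reads / 1_000_000.0
    counts = tpm.mul(kb, axis=0) * (spec.exonic_ratio * millions)
    meta = {
        "populations": populations,
        "total_reads": {s: spec.total_reads for s in samples},
        "exonic_ratios": {s: spec.exonic_ratio for s in samples},
    }
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "population", "fold"])
    return counts, meta, truth
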