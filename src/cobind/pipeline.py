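"""End-to-end orchestration: simulate -> overlap/hotspots -> motifs ->
targets/enrichment -> expression -> rearrangement, with a reproducible
report directory.

Every emitted table starts with ``#`` header lines recording the exact
parameters and seeds used, and re-running the same config yields
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenomicInterval, PeakSet
from .expression import ExpressionTable, make_population_sets, select_enriched_genes
from .io import write_bed, write_fasta, write_gene_table
from .motifs import matched_random_peaks, motif_enrichment, pwm_from_consensus, scan_pwm
from .overlap import find_hotspots, overlap_pvalue, pairwise_overlap
from .rearrange import (
    LocusFeature,
    RearrangementPlan,
    apply_rearrangement,
    plan_summary,
    predict_contacts,
)
from .simulate import (
    CobindingSpec,
    ExpressionSpec,
    plant_motifs,
    simulate_expression,
    simulate_genome,
    simulate_peaks,
)
from .targets import assign_targets, build_domains, region_enrichment

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Full-pipeline configuration; defaults mirror the printed analysis
    constants (150 bp overlap window, 1 kb hotspot window, +/-500 kb domains,
    fold 3 / TPM 5 / alpha 0.05 differential filter, TPM 10 / fold 2 lists).
    """

    seed: int = 0
    out_dir: str = "cobind_run"
    # simulation scale
    n_chroms: int = 2
    chrom_len: int = 400_000
    n_genes: int = 60
    factors: tuple[str, ...] = ("factorA", "factorB", "factorC", "factorD")
    n_anchors: int = 40
    n_specific: int = 40
    jitter_sd: float = 50.0
    accessible_fraction: float = 0.15
    # analysis windows / thresholds
    max_center_dist: int = 150
    hotspot_window: int = 1_000
    domain_mode: str = "flank_500kb"
    domain_flank: int = 500_000
    motif_consensus: str = "TCAGGTTTCA"
    motif_plant_prob: float = 0.5
    motif_window: int = 150
    n_matched_sets: int = 5
    n_random_gene_lists: int = 20
    diff_fold: float = 3.0
    diff_min_tpm: float = 5.0
    diff_alpha: float = 0.05
    set_min_tpm: float = 10.0
    set_fold: float = 2.0
    populations: tuple[str, ...] = ("progenitor", "self_renewing", "differentiating")
    expression_fold_effect: float = 8.0
    expression_planted: int = 10
    expression_dispersion: float = 0.3
    replicates: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("factors", "populations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _header(config: RunConfig, stage: str) -> str:
    params = json.dumps(asdict(config), sort_keys=True)
    return f"# cobind {__version__} stage={stage}\n# config={params}\n"


def _write_table(path: Path, df: pd.DataFrame, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, stage))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on freshly simulated data; returns the report dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- simulate ---------------------------------------------------------
    genome, genes, sequences = simulate_genome(
        config.n_chroms, config.chrom_len, config.n_genes, rng
    )
    spec = CobindingSpec(
        factors=config.factors,
        n_anchors=config.n_anchors,
        n_specific={f: config.n_specific for f in config.factors},
        jitter_sd=config.jitter_sd,
        accessible_fraction=config.accessible_fraction,
        seed=int(rng.integers(0, 2**31)),
    )
    peak_sets, peak_truth, accessible = simulate_peaks(spec, genome)
    first_factor = config.factors[0]
    sequences, motif_truth = plant_motifs(
        sequences,
        peak_sets[first_factor],
        config.motif_consensus,
        config.motif_plant_prob,
        positional_sd=20.0,
        seed=rng,
    )
    expr_spec = ExpressionSpec(
        populations=config.populations,
        n_genes=config.n_genes,
        planted={p: (config.expression_planted, config.expression_fold_effect) for p in config.populations},
        replicates=config.replicates,
        dispersion=config.expression_dispersion,
    )
    counts, meta, expr_truth = simulate_expression(expr_spec, genes, rng)

    write_gene_table(out / "genes.tsv", genes)
    write_fasta(out / "genome.fa", sequences)
    for factor, ps in peak_sets.items():
        write_bed(out / f"peaks_{factor}.bed", ps)
    write_bed(out / "accessible.bed", list(accessible.regions), name="accessible")
    peak_truth.to_csv(truth_dir / "peaks.tsv", sep="\t", index=False)
    motif_truth.to_csv(truth_dir / "motifs.tsv", sep="\t", index=False)
    expr_truth.to_csv(truth_dir / "expression.tsv", sep="\t", index=False)

    # --- overlap + hotspots ----------------------------------------------
    rows = []
    for fa in config.factors:
        for fb in config.factors:
            if fa == fb:
                continue
            n_ab, _ = pairwise_overlap(peak_sets[fa], peak_sets[fb], config.max_center_dist)
            t = overlap_pvalue(
                len(peak_sets[fa]), n_ab, len(peak_sets[fb]),
                accessible.total_size, config.max_center_dist,
            )
            rows.append(
                {
                    "set_A": fa, "set_B": fb, "N_A": t.n_a, "N_B": t.n_b,
                    "N_AB": t.n_ab, "p_B": t.p_b, "expected": t.expected,
                    "fold": t.fold, "neg_log10_p": t.neg_log10_p,
                }
            )
    _write_table(out / "overlap_tests.tsv", pd.DataFrame(rows), config, "overlap")

    hotspots = find_hotspots(peak_sets, window=config.hotspot_window)
    hs_rows = [
        {
            "chrom": h.interval.chrom, "start": h.interval.start, "end": h.interval.end,
            "n_factors": h.n_factors,
            "members": ";".join(f"{f}:{i}" for f, i in sorted(h.members.items())),
        }
        for h in hotspots
    ]
    _write_table(out / "hotspots.tsv", pd.DataFrame(hs_rows), config, "hotspots")

    # --- motif enrichment -------------------------------------------------
    pwm = pwm_from_consensus("planted", config.motif_consensus)
    threshold = pwm.max_score() - 1e-9
    occs = scan_pwm(sequences, pwm, threshold=threshold)
    matched_sets, matched_occs = [], []
    for _ in range(config.n_matched_sets):
        ms = matched_random_peaks(peak_sets[first_factor], genes, genome, rng)
        matched_sets.append(ms)
        matched_occs.append(occs)  # same genomic scan, counted against each matched set
    mt = motif_enrichment(
        peak_sets[first_factor], occs, matched_occs, motif_len=len(pwm),
        matched_peak_sets=matched_sets, window=config.motif_window,
    )
    _write_table(
        out / "motif_enrichment.tsv",
        pd.DataFrame(
            [
                {
                    "factor": first_factor, "motif": pwm.name, "N_A": mt.n_a,
                    "N_Am": mt.n_am, "N_m": mt.n_m, "p_m": mt.p_m,
                    "coverage": mt.coverage, "neg_log10_p": mt.neg_log10_p,
                    "n_matched_sets": mt.n_matched_sets,
                }
            ]
        ),
        config,
        "motif",
    )

    # --- targets + region enrichment -------------------------------------
    domains = build_domains(genes, genome, mode=config.domain_mode, flank=config.domain_flank)
    target_sets = {}
    for factor, ps in peak_sets.items():
        assignment = assign_targets(ps, domains, genes)
        target_sets[factor] = assignment.target_genes()
    from .overlap import core_targets

    core = core_targets(target_sets)
    (out / "core_targets.txt").write_text("\n".join(sorted(core)) + "\n")

    gene_ids = genes.gene_ids
    some_genes = gene_ids[: max(3, len(gene_ids) // 5)]
    rt = region_enrichment(
        peak_sets[first_factor], some_genes, domains, genome,
        n_random=config.n_random_gene_lists, seed=rng,
    )
    _write_table(
        out / "region_enrichment.tsv",
        pd.DataFrame(
            [
                {
                    "set": first_factor, "n_genes": len(some_genes), "N_A": rt.n_a,
                    "N_Ax": rt.n_ax, "p_x": rt.p_x, "r_Ax": rt.r_ax,
                    "expected": rt.expected, "fold": rt.fold,
                    "neg_log10_p": rt.neg_log10_p,
                }
            ]
        ),
        config,
        "targets",
    )

    # --- expression -------------------------------------------------------
    table = ExpressionTable.from_annotation(
        counts,
        meta["populations"],
        meta["total_reads"],
        meta["exonic_ratios"],
        genes,
    )
    pop_a, pop_b = config.populations[0], config.populations[1]
    set_a, set_b = select_enriched_genes(
        table, pop_a, pop_b,
        fold=config.diff_fold, min_tpm=config.diff_min_tpm, alpha=config.diff_alpha,
    )
    lists = make_population_sets(
        table,
        [
            (f"{p}_enriched", p, config.populations[(i + 1) % len(config.populations)])
            for i, p in enumerate(config.populations)
        ],
        min_tpm=config.set_min_tpm,
        fold=config.set_fold,
    )
    expr_rows = [{"set": set_a.name, "n": len(set_a), "genes": ";".join(set_a.members)}]
    expr_rows.append({"set": set_b.name, "n": len(set_b), "genes": ";".join(set_b.members)})
    for name, members in lists.items():
        expr_rows.append({"set": name, "n": len(members), "genes": ";".join(members)})
    _write_table(out / "expression_sets.tsv", pd.DataFrame(expr_rows), config, "expression")

    # --- rearrangement demo ----------------------------------------------
    chrom = genome.chroms[0]
    features = [
        LocusFeature("DE", "enhancer", GenomicInterval(chrom, 1_000, 1_500)),
        LocusFeature("promA", "promoter_tss", GenomicInterval(chrom, 20_000, 20_200)),
        LocusFeature("tad_boundary", "boundary", GenomicInterval(chrom, 40_000, 41_000)),
        LocusFeature("promB", "promoter_tss", GenomicInterval(chrom, 60_000, 60_200)),
    ]
    plan = RearrangementPlan(
        chrom=chrom,
        inversion=GenomicInterval(chrom, 10_000, 50_000),
        deletions=(GenomicInterval(chrom, 55_000, 55_500),),
    )
    remapped, report = apply_rearrangement(features, plan)
    contact_rows = []
    for label, feats in (("wildtype", features), ("rearranged", remapped)):
        for c in predict_contacts(feats):
            contact_rows.append(
                {
                    "axis": label, "enhancer": c.enhancer, "promoter": c.promoter,
                    "allowed": c.allowed, "separation": c.separation,
                    "blocking": ";".join(c.blocking_boundaries),
                }
            )
    _write_table(out / "contacts.tsv", pd.DataFrame(contact_rows), config, "rearrange")
    summary_rows = [
        {"element": r["element"], "bp": r["bp"]} for r in plan_summary(plan)
    ]
    _write_table(out / "plan_summary.tsv", pd.DataFrame(summary_rows), config, "rearrange")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_hotspots": len(hotspots),
        "n_core_targets": len(core),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
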