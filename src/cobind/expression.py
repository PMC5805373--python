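"""Expression quantification (RPKM / exonic-ratio TPM), threshold-based
differential gene sets, and target-category fraction tables.

TPM here follows the source convention: RPKM divided by the library's exonic
mapping ratio, so a sample with half its reads in exons gets doubled values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneAnnotation

__all__ = [
    "ExpressionTable",
    "EnrichedGeneSet",
    "compute_tpm",
    "select_enriched_genes",
    "make_population_sets",
    "category_fraction",
]


def compute_tpm(
    counts: pd.DataFrame,
    exonic_bp: pd.Series,
    total_reads: pd.Series,
    exonic_ratios: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (rpkm, tpm) matrices.

    RPKM = count / (exonic kb * mapped millions); TPM = RPKM / exonic ratio.
    Scaling all counts and the total of one sample by c leaves TPM unchanged.
    """
    exonic_bp = exonic_bp.reindex(counts.index)
    if (exonic_bp <= 0).any() or exonic_bp.isna().any():
        raise ValueError("every gene needs exonic_bp > 0")
    total_reads = total_reads.reindex(counts.columns)
    if (total_reads <= 0).any() or total_reads.isna().any():
        raise ValueError("every sample needs total mapped reads > 0")
    exonic_ratios = exonic_ratios.reindex(counts.columns)
    if not ((exonic_ratios > 0) & (exonic_ratios <= 1)).all():
        raise ValueError("exonic mapping ratios must be in (0, 1]")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    kb = exonic_bp / 1_000.0
    millions = total_reads / 1_000_000.0
    rpkm = counts.div(kb, axis=0).div(millions, axis=1)
    tpm = rpkm.div(exonic_ratios, axis=1)
    return rpkm, tpm


@dataclass
class ExpressionTable:
    """Counts matrix (genes x samples) with population labels and the
    per-sample normalization inputs; RPKM/TPM derived lazily."""

    counts: pd.DataFrame
    populations: dict[str, str]  # sample -> population
    total_reads: pd.Series
    exonic_ratios: pd.Series
    exonic_bp: pd.Series
    _rpkm: pd.DataFrame | None = field(default=None, repr=False)
    _tpm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.populations)
        if missing:
            raise ValueError(f"samples without population label: {sorted(missing)}")

    @classmethod
    def from_annotation(cls, counts, populations, total_reads, exonic_ratios, genes: GeneAnnotation):
        exonic = pd.Series({g.gene_id: g.exonic_bp for g in genes})
        return cls(counts, populations, pd.Series(total_reads), pd.Series(exonic_ratios), exonic)

    @property
    def rpkm(self) -> pd.DataFrame:
        if self._rpkm is None:
            self._rpkm, self._tpm = compute_tpm(
                self.counts, self.exonic_bp, self.total_reads, self.exonic_ratios
            )
        return self._rpkm

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            _ = self.rpkm
        return self._tpm

    def samples_of(self, population: str) -> list[str]:
        cols = [s for s, p in self.populations.items() if p == population and s in self.counts.columns]
        if not cols:
            raise ValueError(f"no samples for population {population!r}")
        return cols

    @property
    def population_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations.values():
            if p not in seen:
                seen.append(p)
        return seen


@dataclass(frozen=True)
class EnrichedGeneSet:
    name: str
    population: str
    reference: str
    fold_threshold: float
    min_tpm: float
    alpha: float | None
    members: tuple[str, ...]
    fold: dict[str, float] = field(compare=False, default_factory=dict)
    mean_tpm: dict[str, float] = field(compare=False, default_factory=dict)
    test: str = "welch_log2"

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def _population_enriched(
    tpm: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    pop_a: str,
    pop_b: str,
    fold: float,
    min_tpm: float,
    alpha: float | None,
    pseudocount: float,
) -> EnrichedGeneSet:
    mean_a = tpm[cols_a].mean(axis=1)
    mean_b = tpm[cols_b].mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    mask = (mean_a > min_tpm) & (fc > fold)
    use_test = alpha is not None and len(cols_a) >= 2 and len(cols_b) >= 2
    if alpha is not None and not use_test:
        warnings.warn("fewer than 2 replicates per population: p-value filter skipped")
    if use_test and mask.any():
        log_a = np.log2(tpm.loc[mask, cols_a] + 1.0)
        log_b = np.log2(tpm.loc[mask, cols_b] + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p = pd.Series(np.where(np.isnan(p), 1.0, p), index=tpm.index[mask])
        keep = p.index[p < alpha]
        mask = mask & tpm.index.isin(keep)
    members = tuple(tpm.index[mask])
    return EnrichedGeneSet(
        name=f"{pop_a}_enriched",
        population=pop_a,
        reference=pop_b,
        fold_threshold=fold,
        min_tpm=min_tpm,
        alpha=alpha if use_test else None,
        members=members,
        fold={g: float(fc[g]) for g in members},
        mean_tpm={g: float(mean_a[g]) for g in members},
    )


def select_enriched_genes(
    table: ExpressionTable,
    pop_a: str,
    pop_b: str,
    fold: float = 3.0,
    min_tpm: float = 5.0,
    alpha: float | None = 0.05,
    pseudocount: float = 0.01,
) -> tuple[EnrichedGeneSet, EnrichedGeneSet]:
    """Differential sets: mean TPM > min_tpm in the enriched population, mean
    fold > ``fold`` (pseudo-counted), and Welch's test on log2(TPM+1) across
    replicates at ``alpha`` (skipped with a warning for single replicates).

    Returns (A-enriched, B-enriched); the two sets are disjoint by
    construction (fold > 3 one way excludes fold > 3 the other way).
    """
    cols_a = table.samples_of(pop_a)
    cols_b = table.samples_of(pop_b)
    tpm = table.tpm
    set_a = _population_enriched(tpm, cols_a, cols_b, pop_a, pop_b, fold, min_tpm, alpha, pseudocount)
    set_b = _population_enriched(tpm, cols_b, cols_a, pop_b, pop_a, fold, min_tpm, alpha, pseudocount)
    return set_a, set_b


def make_population_sets(
    table: ExpressionTable,
    comparisons: list[tuple[str, str, str]],
    min_tpm: float = 10.0,
    fold: float = 2.0,
    pseudocount: float = 0.01,
) -> dict[str, list[str]]:
    """Threshold-only gene lists: for each (name, pop, ref) the genes with
    mean TPM > min_tpm in ``pop`` and mean fold over ``ref`` strictly > fold.
    """
    tpm = table.tpm
    out: dict[str, list[str]] = {}
    for name, pop, ref in comparisons:
        cols_a = table.samples_of(pop)
        cols_b = table.samples_of(ref)
        mean_a = tpm[cols_a].mean(axis=1)
        mean_b = tpm[cols_b].mean(axis=1)
        fc = (mean_a + pseudocount) / (mean_b + pseudocount)
        mask = (mean_a > min_tpm) & (fc > fold)
        out[name] = list(tpm.index[mask])
    return out


def category_fraction(
    target_sets: dict[str, set[str]],
    categories: dict[str, list[str]],
    transcriptome: list[str],
) -> pd.DataFrame:
    """Percentage of each target set falling in each gene category, with a
    whole-transcriptome baseline row; empty sets get a zero-denominator flag.
    """
    cat_sets = {name: set(genes) for name, genes in categories.items()}
    rows = []
    for set_name, genes in list(target_sets.items()) + [("transcriptome", set(transcriptome))]:
        row: dict[str, object] = {"set": set_name, "n_genes": len(genes)}
        if not genes:
            row["empty"] = True
            for cat in cat_sets:
                row[cat] = math.nan
        else:
            row["empty"] = False
            for cat, members in cat_sets.items():
                row[cat] = 100.0 * len(genes & members) / len(genes)
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
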