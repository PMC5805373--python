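"""Gene annotation records (TSS + strand + exonic length)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .core import GenomeModel

__all__ = ["GeneRecord", "GeneAnnotation"]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exonic_bp: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")
        if self.exonic_bp <= 0:
            raise ValueError("exonic_bp must be positive")


class GeneAnnotation:
    """Collection of genes indexed by id, with per-chromosome sorted TSS arrays."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in annotation")
        self._by_id = {g.gene_id: g for g in self.genes}
        self._tss_index: dict[str, tuple[np.ndarray, list[GeneRecord]]] = {}
        for g in self.genes:
            self._tss_index.setdefault(g.chrom, (None, []))  # type: ignore[arg-type]
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._tss_index[chrom] = (np.array([g.tss for g in gs]), gs)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def on_chrom(self, chrom: str) -> list[GeneRecord]:
        return self._tss_index.get(chrom, (np.array([]), []))[1]

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneRecord, int]:
        """Return (gene, signed distance) of the nearest TSS to ``pos``.

        The distance is signed relative to gene orientation: positive means
        ``pos`` lies downstream of the TSS, negative upstream.  Ties go to the
        gene with the smaller TSS coordinate.
        """
        if chrom not in self._tss_index:
            raise ValueError(f"no genes on chromosome {chrom!r}")
        tss_arr, gs = self._tss_index[chrom]
        i = int(np.searchsorted(tss_arr, pos))
        best: GeneRecord | None = None
        best_abs = None
        for j in (i - 1, i):
            if 0 <= j < len(gs):
                d = abs(pos - gs[j].tss)
                if best is None or d < best_abs:
                    best, best_abs = gs[j], d
        assert best is not None
        offset = pos - best.tss
        signed = offset if best.strand == "+" else -offset
        return best, signed

    def validate_against(self, genome: GenomeModel) -> None:
        for g in self.genes:
            if g.chrom not in genome:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.tss >= genome.chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.gene_id}: TSS beyond end of {g.chrom}")
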