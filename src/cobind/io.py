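"""Plain-text readers and writers: BED4/BED6/narrowPeak, gene tables, FASTA.

All BED coordinates are 0-based half-open, both on read and write.  Files
written with ``paper_inclusive`` convention are converted on read so that the
in-memory representation is always half-open.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

from .core import GenomeModel, GenomicInterval, PeakSet
from .genes import GeneAnnotation, GeneRecord

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
]

GENE_TABLE_COLUMNS = ("gene_id", "chrom", "strand", "tss", "exonic_bp")


class BedParseError(ValueError):
    def __init__(self, path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.path = path
        self.lineno = lineno


def _parse_bed_line(path, lineno: int, line: str, convention: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(path, lineno, f"non-integer coordinates: {fields[1]!r}, {fields[2]!r}")
    if convention == "paper_inclusive":
        start -= 1
    score = math.nan
    if len(fields) >= 5 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise BedParseError(path, lineno, f"non-numeric score: {fields[4]!r}")
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(chrom, start, end, strand, score)
    except ValueError as e:
        raise BedParseError(path, lineno, str(e))


def read_bed(
    path,
    name: str | None = None,
    source_convention: str = "bed_half_open",
    genome: GenomeModel | None = None,
) -> PeakSet:
    """Read a BED3/4/5/6 (or narrowPeak) file into a :class:`PeakSet`.

    Malformed lines raise :class:`BedParseError` with the line number; unknown
    chromosomes (when ``genome`` is given) are an error too.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(path, lineno, line, source_convention)
            if genome is not None:
                try:
                    genome.check_interval(iv)
                except ValueError as e:
                    raise BedParseError(path, lineno, str(e))
            intervals.append(iv)
    return PeakSet(name or path.stem, intervals, source_convention="bed_half_open")


def write_bed(path, peaks: PeakSet | Iterable[GenomicInterval], name: str | None = None) -> None:
    """Write BED6; score written as '.' when NaN (scoreless, not zero)."""
    ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    label = name or (peaks.name if isinstance(peaks, PeakSet) else "region")
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            score = "." if math.isnan(iv.score) else repr(iv.score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}_{i}\t{score}\t{iv.strand}\n")


def read_narrowpeak(path, name: str | None = None, genome: GenomeModel | None = None) -> PeakSet:
    """narrowPeak is BED6+4; the extra columns are not consumed."""
    return read_bed(path, name=name, genome=genome)


def write_narrowpeak(path, peaks: PeakSet) -> None:
    """Write BED6+4 narrowPeak; signalValue carries the score, summit = center offset."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            score_col = 0 if math.isnan(iv.score) else int(min(1000, max(0, iv.score)))
            signal = "0" if math.isnan(iv.score) else repr(iv.score)
            summit = (iv.start + iv.end) // 2 - iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.name}_{i}\t{score_col}\t{iv.strand}"
                f"\t{signal}\t-1\t-1\t{summit}\n"
            )


def read_gene_table(path, genome: GenomeModel | None = None) -> GeneAnnotation:
    """Read the tab-delimited gene table (gene_id, chrom, strand, tss, exonic_bp[, symbol])."""
    path = Path(path)
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 5:
                raise BedParseError(path, lineno, f"expected >=5 fields, got {len(fields)}")
            try:
                rec = GeneRecord(
                    gene_id=fields[0],
                    chrom=fields[1],
                    strand=fields[2],
                    tss=int(fields[3]),
                    exonic_bp=int(fields[4]),
                    symbol=fields[5] if len(fields) > 5 and fields[5] else None,
                )
            except ValueError as e:
                raise BedParseError(path, lineno, str(e))
            if genome is not None and rec.chrom not in genome:
                raise BedParseError(path, lineno, f"unknown chromosome {rec.chrom!r}")
            genes.append(rec)
    return GeneAnnotation(genes)


def write_gene_table(path, genes: GeneAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS + ("symbol",)) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.exonic_bp}\t{g.symbol or ''}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader returning upper-cased sequences keyed by first word of header."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise ValueError(f"duplicate FASTA record {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise ValueError("FASTA sequence before first header")
                seqs[current].append(line.upper())
    return {name: "".join(parts) for name, parts in seqs.items()}


def write_fasta(path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
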