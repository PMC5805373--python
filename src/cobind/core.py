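"""Coordinate conventions and interval arithmetic shared by all stages.

Internally every interval is 0-based half-open ``[start, end)``.  Human-readable
coordinate strings (``chr17:85414584-85419213``) are 1-based with inclusive
endpoints, which is the only convention under which the printed lengths of the
worked deletion examples come out exact.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GenomeModel",
    "CoordinateParseError",
    "parse_paper_coordinate",
    "format_paper_coordinate",
    "interval_length",
    "center",
    "merge_intervals",
    "total_coverage",
]

STRANDS = ("+", "-", ".")

# accepts ASCII hyphen, en dash and minus sign between the two endpoints
_COORD_RE = re.compile(r"^\s*([^\s:]+):(\d+)\s*[-–−]\s*(\d+)\s*$")


class CoordinateParseError(ValueError):
    """Raised for malformed 1-based coordinate strings."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``score`` defaults to NaN (absent), never 0: a 0 score is a real value.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = field(default=math.nan, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def parse_paper_coordinate(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` string into an interval.

    ``chr1:100-100`` denotes the single base 100 and yields a length-1
    interval.  Round-trips through :func:`format_paper_coordinate`.
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise CoordinateParseError(f"malformed coordinate string: {text!r}")
    chrom, start_s, end_s = m.groups()
    start1, end1 = int(start_s), int(end_s)
    if start1 < 1:
        raise CoordinateParseError(f"1-based start must be >= 1: {text!r}")
    if start1 > end1:
        raise CoordinateParseError(f"start exceeds end in {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_paper_coordinate(iv: GenomicInterval, dash: str = "-") -> str:
    """Inverse of :func:`parse_paper_coordinate` (1-based inclusive output)."""
    return f"{iv.chrom}:{iv.start + 1}{dash}{iv.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp under the half-open convention (``end - start``)."""
    return iv.end - iv.start


def center(iv: GenomicInterval) -> int:
    """Peak center, floored on odd lengths."""
    return (iv.start + iv.end) // 2


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint interval set with the same per-base coverage.

    Strand and score are not preserved (merged output is unstranded).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_coverage(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of ``intervals``."""
    return sum(len(iv) for iv in merge_intervals(intervals))


class PeakSet:
    """A named set of peaks; ``len(peak_set)`` is the N used in binomial trials.

    Intervals are kept sorted by ``(chrom, start, end)``.
    """

    def __init__(
        self,
        name: str,
        intervals: Iterable[GenomicInterval],
        source_convention: str = "bed_half_open",
    ):
        if source_convention not in ("bed_half_open", "paper_inclusive"):
            raise ValueError(f"unknown source_convention {source_convention!r}")
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.source_convention = source_convention

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.name == other.name and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.name!r}, n={len(self)})"

    def centers(self) -> list[int]:
        return [center(iv) for iv in self.intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def validate_against(self, genome: "GenomeModel") -> None:
        for iv in self.intervals:
            genome.check_interval(iv)


class GenomeModel:
    """Chromosome sizes and the derived total genome size."""

    def __init__(self, chrom_sizes: dict[str, int]):
        if not chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        self.chrom_sizes = dict(chrom_sizes)

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv} extends past end of {iv.chrom} "
                f"({self.chrom_sizes[iv.chrom]} bp)"
            )

    def clip(self, iv: GenomicInterval) -> GenomicInterval | None:
        """Clip an interval to chromosome bounds; None if nothing survives."""
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        start = max(0, iv.start)
        end = min(self.chrom_sizes[iv.chrom], iv.end)
        if start >= end:
            return None
        return GenomicInterval(iv.chrom, start, end, iv.strand, iv.score)
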