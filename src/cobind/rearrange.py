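"""Structural-rearrangement modeling: apply an inversion plus deletions to an
annotated locus, re-map features, and predict boundary-constrained
enhancer-promoter contacts on wild-type or rearranged axes.

Contact rules are topological, not metric: a pair is blocked when a
boundary-kind feature lies strictly between the enhancer center and the
promoter TSS on the current axis, regardless of separation.  Separation only
enters through the optional ``max_range`` cut-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GenomicInterval, interval_length, merge_intervals, parse_paper_coordinate

__all__ = [
    "LocusFeature",
    "RearrangementPlan",
    "ContactPrediction",
    "map_position",
    "map_positions",
    "apply_rearrangement",
    "predict_contacts",
    "plan_summary",
]

FEATURE_KINDS = ("enhancer", "promoter_tss", "boundary", "gene_body", "other")
DELETED = -1


@dataclass(frozen=True)
class LocusFeature:
    name: str
    kind: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class RearrangementPlan:
    """Inversion plus disjoint deletions, all in original coordinates on one
    chromosome.  ``order`` controls composition: with ``deletions_first`` the
    inversion acts on the post-deletion axis (its own endpoints mapped
    through the deletion shift); with ``inversion_first`` the deletions are
    carried through the inversion before being removed.
    """

    chrom: str
    inversion: GenomicInterval | None = None
    deletions: tuple[GenomicInterval, ...] = ()
    order: str = "deletions_first"

    def __post_init__(self) -> None:
        if self.order not in ("deletions_first", "inversion_first"):
            raise ValueError(f"unknown application order {self.order!r}")
        for iv in self.deletions:
            if iv.chrom != self.chrom:
                raise ValueError("deletion on a different chromosome than the plan")
        if self.inversion is not None and self.inversion.chrom != self.chrom:
            raise ValueError("inversion on a different chromosome than the plan")
        dels = sorted(self.deletions, key=lambda iv: iv.start)
        for a, b in zip(dels, dels[1:]):
            if b.start < a.end:
                raise ValueError("deletions must be disjoint")

    @property
    def deleted_bp(self) -> int:
        return sum(len(iv) for iv in self.deletions)

    @classmethod
    def from_json(cls, payload) -> "RearrangementPlan":
        """Plan from a JSON dict/string; coordinates either half-open
        {"start":..,"end":..} pairs or 1-based inclusive strings."""
        if isinstance(payload, str):
            payload = json.loads(payload)

        def _iv(entry, chrom):
            if isinstance(entry, str):
                return parse_paper_coordinate(entry)
            return GenomicInterval(entry.get("chrom", chrom), entry["start"], entry["end"])

        chrom = payload["chrom"]
        inversion = _iv(payload["inversion"], chrom) if payload.get("inversion") else None
        deletions = tuple(_iv(d, chrom) for d in payload.get("deletions", []))
        return cls(
            chrom=chrom,
            inversion=inversion,
            deletions=deletions,
            order=payload.get("order", "deletions_first"),
        )

    def to_json(self) -> str:
        payload = {
            "chrom": self.chrom,
            "inversion": (
                {"start": self.inversion.start, "end": self.inversion.end}
                if self.inversion
                else None
            ),
            "deletions": [{"start": d.start, "end": d.end} for d in self.deletions],
            "order": self.order,
        }
        return json.dumps(payload, indent=1)


def _delete_shift(positions: np.ndarray, deletions: tuple[GenomicInterval, ...]) -> np.ndarray:
    """Map original positions through deletions: DELETED flag or left shift."""
    out = positions.copy()
    deleted = np.zeros(len(positions), dtype=bool)
    shift = np.zeros(len(positions), dtype=np.int64)
    for d in deletions:
        inside = (positions >= d.start) & (positions < d.end)
        deleted |= inside
        shift += np.where(positions >= d.end, len(d), 0)
    out = out - shift
    out[deleted] = DELETED
    return out


def _invert(positions: np.ndarray, inv_start: int, inv_end: int) -> np.ndarray:
    out = positions.copy()
    inside = (positions >= inv_start) & (positions < inv_end) & (positions != DELETED)
    out[inside] = inv_start + (inv_end - 1 - positions[inside])
    return out


def _split_interval_at(iv: GenomicInterval, cuts: list[int]) -> list[GenomicInterval]:
    points = sorted({c for c in cuts if iv.start < c < iv.end})
    bounds = [iv.start] + points + [iv.end]
    return [GenomicInterval(iv.chrom, a, b) for a, b in zip(bounds, bounds[1:])]


def map_positions(positions: np.ndarray, plan: RearrangementPlan) -> np.ndarray:
    """Vectorized position map; deleted bases come back as ``DELETED`` (-1).

    Bijective on surviving bases.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if plan.order == "deletions_first":
        out = _delete_shift(positions, plan.deletions)
        if plan.inversion is not None:
            # the image of [s, e) on the post-deletion axis is the contiguous
            # [s - del_below(s), e - del_below(e)) where del_below(p) counts
            # deleted bases strictly below p
            def _shifted(pos: int) -> int:
                removed = sum(
                    max(0, min(d.end, pos) - d.start) for d in plan.deletions
                )
                return pos - removed

            lo = _shifted(plan.inversion.start)
            hi = _shifted(plan.inversion.end)
            if hi > lo:
                out = _invert(out, int(lo), int(hi))
        return out
    # inversion first, then deletions carried through the inversion
    out = positions.copy()
    if plan.inversion is not None:
        out = _invert(out, plan.inversion.start, plan.inversion.end)
    mapped_deletions: list[GenomicInterval] = []
    for d in plan.deletions:
        pieces = (
            _split_interval_at(d, [plan.inversion.start, plan.inversion.end])
            if plan.inversion is not None
            else [d]
        )
        for piece in pieces:
            ends = _invert(
                np.array([piece.start, piece.end - 1]),
                plan.inversion.start if plan.inversion else 0,
                plan.inversion.end if plan.inversion else 0,
            )
            lo, hi = int(min(ends)), int(max(ends)) + 1
            mapped_deletions.append(GenomicInterval(plan.chrom, lo, hi))
    merged = merge_intervals(mapped_deletions) if mapped_deletions else []
    return _delete_shift(out, tuple(merged))


def map_position(pos: int, plan: RearrangementPlan) -> int:
    """Single-position map; returns ``DELETED`` (-1) for removed bases."""
    return int(map_positions(np.array([pos]), plan)[0])


@dataclass
class RearrangementReport:
    dropped: list[str] = field(default_factory=list)
    split: list[str] = field(default_factory=list)
    inverted: list[str] = field(default_factory=list)
    boundary_side_changes: list[dict] = field(default_factory=list)


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


def apply_rearrangement(
    features: list[LocusFeature], plan: RearrangementPlan
) -> tuple[list[LocusFeature], RearrangementReport]:
    """Re-map locus features through ``plan``.

    Fully surviving contiguous features come back intact (strand flipped when
    inverted); features whose surviving bases land in several runs are split
    into ``name.part1..k`` pieces and flagged; fully deleted features are
    dropped with a report entry.  The report also lists every feature whose
    side relative to a boundary feature changed.
    """
    report = RearrangementReport()
    remapped: list[LocusFeature] = []
    for f in features:
        if f.interval.chrom != plan.chrom:
            remapped.append(f)
            continue
        positions = np.arange(f.interval.start, f.interval.end, dtype=np.int64)
        images = map_positions(positions, plan)
        surviving = images[images != DELETED]
        if surviving.size == 0:
            report.dropped.append(f.name)
            continue
        ordered = np.sort(surviving)
        breaks = np.nonzero(np.diff(ordered) != 1)[0]
        run_bounds = np.concatenate(([0], breaks + 1, [ordered.size]))
        runs = [
            (int(ordered[a]), int(ordered[b - 1]) + 1)
            for a, b in zip(run_bounds, run_bounds[1:])
        ]
        # a run is inverted when the map reverses order within it
        first_img = images[images != DELETED][0]
        last_img = images[images != DELETED][-1]
        inverted = last_img < first_img
        strand = _flip(f.interval.strand) if inverted else f.interval.strand
        if len(runs) == 1:
            newf = LocusFeature(
                f.name,
                f.kind,
                GenomicInterval(plan.chrom, runs[0][0], runs[0][1], strand, f.interval.score),
            )
            remapped.append(newf)
            if inverted:
                report.inverted.append(f.name)
        else:
            report.split.append(f.name)
            for k, (lo, hi) in enumerate(runs, start=1):
                remapped.append(
                    LocusFeature(
                        f"{f.name}.part{k}",
                        f.kind,
                        GenomicInterval(plan.chrom, lo, hi, strand, f.interval.score),
                    )
                )

    boundaries_before = [f for f in features if f.kind == "boundary"]
    for b in boundaries_before:
        b_after = [f for f in remapped if f.name.split(".part")[0] == b.name]
        if not b_after:
            continue
        b_pos_before = b.interval.center
        b_pos_after = b_after[0].interval.center
        for f in features:
            if f.kind == "boundary" or f.interval.chrom != plan.chrom:
                continue
            f_after = [g for g in remapped if g.name.split(".part")[0] == f.name]
            if not f_after:
                continue
            before_side = "left" if f.interval.center < b_pos_before else "right"
            after_side = "left" if f_after[0].interval.center < b_pos_after else "right"
            if before_side != after_side:
                report.boundary_side_changes.append(
                    {"feature": f.name, "boundary": b.name, "from": before_side, "to": after_side}
                )
    return remapped, report


@dataclass(frozen=True)
class ContactPrediction:
    enhancer: str
    promoter: str
    allowed: bool
    blocking_boundaries: tuple[str, ...]
    separation: int


def predict_contacts(
    features: list[LocusFeature], max_range: float = float("inf")
) -> list[ContactPrediction]:
    """Enhancer-promoter contact predictions on the current axis.

    A pair is allowed iff no boundary feature lies with its full interval
    strictly between the enhancer center and the promoter TSS center
    (touching either end point does not block) and the separation is within
    ``max_range``.  Distance never decides blocking on its own.
    """
    enhancers = sorted(
        (f for f in features if f.kind == "enhancer"), key=lambda f: f.name
    )
    promoters = sorted(
        (f for f in features if f.kind == "promoter_tss"), key=lambda f: f.name
    )
    boundaries = [f for f in features if f.kind == "boundary"]
    if not enhancers or not promoters:
        raise ValueError("need at least one enhancer and one promoter feature")
    out: list[ContactPrediction] = []
    for e in enhancers:
        for p in promoters:
            if e.interval.chrom != p.interval.chrom:
                continue
            lo, hi = sorted((e.interval.center, p.interval.center))
            blocking = tuple(
                sorted(
                    b.name
                    for b in boundaries
                    if b.interval.chrom == e.interval.chrom
                    and b.interval.start > lo
                    and b.interval.end - 1 < hi
                )
            )
            separation = hi - lo
            out.append(
                ContactPrediction(
                    enhancer=e.name,
                    promoter=p.name,
                    allowed=(not blocking) and separation <= max_range,
                    blocking_boundaries=blocking,
                    separation=separation,
                )
            )
    return out


def plan_summary(plan: RearrangementPlan) -> list[dict]:
    """Sizes table: one row per plan element with its bp length."""
    rows = []
    if plan.inversion is not None:
        rows.append({"element": "inversion", "interval": plan.inversion, "bp": interval_length(plan.inversion)})
    for i, d in enumerate(sorted(plan.deletions, key=lambda iv: iv.start), start=1):
        rows.append({"element": f"deletion_{i}", "interval": d, "bp": interval_length(d)})
    return rows
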