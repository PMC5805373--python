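"""Pairwise/multi-way co-binding detection and the accessible-chromatin
binomial overlap model; regulatory-hotspot calling.

The null model: a peak lands uniformly in accessible chromatin (merged
ATAC regions extended +/-150 bp each side), and two peaks overlap when their
centers are strictly closer than ``max_center_dist`` (default 150 bp).  The
per-peak hit probability is then ``window * N_B / accessible_size`` with
``window = 2 * max_center_dist`` — the overlap window length.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import numpy as np

from .binomial import binom_log_sf
from .core import GenomeModel, GenomicInterval, PeakSet, center, merge_intervals

__all__ = [
    "AccessibleChromatin",
    "OverlapTest",
    "Hotspot",
    "build_accessible",
    "pairwise_overlap",
    "overlap_pvalue",
    "find_hotspots",
    "target_set_overlap_ratio",
    "core_targets",
    "score_by_cobinding",
]


@dataclass(frozen=True)
class AccessibleChromatin:
    """Merged accessible regions and their total size (the null territory)."""

    regions: tuple[GenomicInterval, ...]
    total_size: int

    def __post_init__(self) -> None:
        if self.total_size != sum(len(r) for r in self.regions):
            raise ValueError("total_size inconsistent with regions")


@dataclass(frozen=True)
class OverlapTest:
    """Directional overlap significance of peak set A against set B."""

    n_a: int
    n_b: int
    n_ab: int
    p_b: float
    expected: float
    p_value: float
    neg_log10_p: float
    fold: float = math.nan

    def __post_init__(self) -> None:
        if not (0 <= self.n_ab <= self.n_a):
            raise ValueError("need 0 <= N_AB <= N_A")


@dataclass(frozen=True)
class Hotspot:
    """A group of co-located peaks, one per factor, within the window rule."""

    interval: GenomicInterval
    members: dict[str, int] = field(compare=False)  # factor -> peak index
    n_factors: int = 0


def build_accessible(
    atac_peaks: PeakSet, genome: GenomeModel, extend: int = 150
) -> AccessibleChromatin:
    """Extend ATAC peaks by ``extend`` bp both sides, merge, clip to chromosomes."""
    if len(atac_peaks) == 0:
        raise ValueError("empty ATAC peak set: accessible-chromatin null undefined")
    extended = []
    for iv in atac_peaks:
        clipped = genome.clip(
            GenomicInterval(iv.chrom, max(0, iv.start - extend), iv.end + extend)
        )
        if clipped is not None:
            extended.append(clipped)
    regions = tuple(merge_intervals(extended))
    return AccessibleChromatin(regions, sum(len(r) for r in regions))


def pairwise_overlap(
    a: PeakSet, b: PeakSet, max_center_dist: int = 150
) -> tuple[int, list[tuple[int, int]]]:
    """Count A peaks with >=1 B peak at center distance strictly < ``max_center_dist``.

    Returns ``(N_AB, pairs)`` where pairs lists every qualifying (a_index,
    b_index).  Asymmetric: counted in A's frame.
    """
    b_centers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, iv in enumerate(b):
        b_centers.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    tmp: dict[str, list[tuple[int, int]]] = {}
    for j, iv in enumerate(b):
        tmp.setdefault(iv.chrom, []).append((center(iv), j))
    for chrom, pairs_ in tmp.items():
        pairs_.sort()
        b_centers[chrom] = (
            np.array([c for c, _ in pairs_]),
            np.array([j for _, j in pairs_]),
        )

    n_ab = 0
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        if iv.chrom not in b_centers:
            continue
        centers_arr, idx_arr = b_centers[iv.chrom]
        c = center(iv)
        lo = int(np.searchsorted(centers_arr, c - max_center_dist, side="right"))
        hi = int(np.searchsorted(centers_arr, c + max_center_dist, side="left"))
        if hi > lo:
            n_ab += 1
            pairs.extend((i, int(j)) for j in idx_arr[lo:hi])
    return n_ab, pairs


def overlap_pvalue(
    n_a: int,
    n_ab: int,
    n_b: int,
    accessible_size: int,
    max_center_dist: int = 150,
) -> OverlapTest:
    """Binomial overlap test: N_AB ~ Binom(N_A, p_B), p_B = window*N_B/accessible_size."""
    if accessible_size <= 0:
        raise ValueError("accessible_size must be positive")
    if n_ab > n_a:
        raise ValueError(f"N_AB ({n_ab}) exceeds N_A ({n_a})")
    window = 2 * max_center_dist
    p_b = window * n_b / accessible_size
    if p_b > 1.0:
        import warnings

        warnings.warn(
            f"p_B = {p_b:.3g} exceeds 1; capping (accessible chromatin saturated)"
        )
        p_b = 1.0
    log_sf = binom_log_sf(n_ab, n_a, p_b)
    expected = n_a * p_b
    fold = n_ab / expected if expected > 0 else math.nan
    return OverlapTest(
        n_a=n_a,
        n_b=n_b,
        n_ab=n_ab,
        p_b=p_b,
        expected=expected,
        # clamped so the float stays in (0,1]; neg_log10_p is the exact report
        p_value=math.exp(max(log_sf, -744.0)),
        neg_log10_p=-log_sf / math.log(10),
        fold=fold,
    )


def find_hotspots(
    peak_sets: dict[str, PeakSet],
    window: int = 1000,
    min_factors: int | None = None,
) -> list[Hotspot]:
    """Greedy left-to-right sweep calling groups of centers within ``window``.

    A hotspot is a group with one peak from each of >= ``min_factors`` distinct
    factors (default: all factors) whose centers all lie within ``window`` of
    each other (clique rule: max - min <= window).  Each peak joins at most one
    hotspot; at each anchor position the leftmost available peak per factor is
    taken.  Output is independent of dict ordering and factor labels.
    """
    if len(peak_sets) < 2:
        raise ValueError("need >=2 factors for hotspot calling")
    required = len(peak_sets) if min_factors is None else min_factors
    if required < 2 or required > len(peak_sets):
        raise ValueError(f"min_factors must be in [2, {len(peak_sets)}]")

    # pooled (chrom, center, start, end, factor, index); factor last so labels
    # only break exact-coordinate ties
    pool = []
    for factor in sorted(peak_sets):
        ps = peak_sets[factor]
        for i, iv in enumerate(ps):
            pool.append((iv.chrom, center(iv), iv.start, iv.end, factor, i))
    pool.sort()

    used = [False] * len(pool)
    hotspots: list[Hotspot] = []
    n = len(pool)
    for anchor in range(n):
        if used[anchor]:
            continue
        chrom, c0 = pool[anchor][0], pool[anchor][1]
        chosen: dict[str, int] = {}  # factor -> pool index
        j = anchor
        while j < n and pool[j][0] == chrom and pool[j][1] - c0 <= window:
            if not used[j] and pool[j][4] not in chosen:
                chosen[pool[j][4]] = j
            j += 1
        if len(chosen) >= required and pool[anchor][4] in chosen:
            centers = [pool[j][1] for j in chosen.values()]
            lo, hi = min(centers), max(centers)
            members = {factor: pool[j][5] for factor, j in chosen.items()}
            hotspots.append(
                Hotspot(
                    interval=GenomicInterval(chrom, lo, hi + 1),
                    members=members,
                    n_factors=len(members),
                )
            )
            for j in chosen.values():
                used[j] = True
    return hotspots


def target_set_overlap_ratio(targets_a: set, targets_b: set) -> float:
    """|A ∩ B| / |A| — the asymmetric target-sharing ratio in A's frame."""
    if not targets_a:
        raise ValueError("empty target set A: ratio undefined")
    return len(targets_a & targets_b) / len(targets_a)


def core_targets(per_factor_targets: dict[str, set]) -> set:
    """Genes targeted by every factor (n-way set intersection)."""
    if len(per_factor_targets) < 2:
        raise ValueError("need >=2 factor target sets")
    sets = list(per_factor_targets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def score_by_cobinding(
    primary: PeakSet,
    others: dict[str, PeakSet],
    max_center_dist: int = 150,
) -> dict[frozenset, dict]:
    """Partition primary-factor peaks by which other factors co-bind them.

    Returns, per co-binding combination (frozenset of other-factor names,
    empty = primary-only), the peak indices, their scores, and summary stats.
    Peaks must carry scores.
    """
    if any(math.isnan(iv.score) for iv in primary):
        raise ValueError("primary peaks must carry scores")
    combo_of: list[set] = [set() for _ in range(len(primary))]
    for factor, ps in others.items():
        _, pairs = pairwise_overlap(primary, ps, max_center_dist)
        for i, _ in pairs:
            combo_of[i].add(factor)
    partitions: dict[frozenset, dict] = {}
    for i, combo in enumerate(combo_of):
        key = frozenset(combo)
        partitions.setdefault(key, {"indices": [], "scores": []})
        partitions[key]["indices"].append(i)
        partitions[key]["scores"].append(primary[i].score)
    for info in partitions.values():
        scores = info["scores"]
        info["n"] = len(scores)
        info["mean"] = statistics.fmean(scores)
        info["median"] = statistics.median(scores)
    return partitions
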