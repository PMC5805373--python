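import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobind.core import GenomicInterval, PeakSet, center
from cobind.overlap import (
    build_accessible,
    core_targets,
    find_hotspots,
    overlap_pvalue,
    pairwise_overlap,
    score_by_cobinding,
    target_set_overlap_ratio,
)

from .conftest import (
    coverage_bitmap,
    exact_binom_neg_log10_upper_tail,
    exact_binom_upper_tail,
    random_peakset,
)

ACCESSIBLE_TOTAL = 21_856_500  # printed accessible-chromatin size, used as a realistic scale


class TestBuildAccessible:
    def test_single_peak_extended(self, toy_genome):
        ps = PeakSet("atac", [GenomicInterval("chr1", 1000, 1200)])
        acc = build_accessible(ps, toy_genome, extend=150)
        assert acc.regions == (GenomicInterval("chr1", 850, 1350),)
        assert acc.total_size == 500

    def test_nearby_peaks_merge(self, toy_genome):
        ps = PeakSet(
            "atac",
            [GenomicInterval("chr1", 1000, 1200), GenomicInterval("chr1", 1300, 1500)],
        )
        acc = build_accessible(ps, toy_genome, extend=150)
        assert len(acc.regions) == 1

    def test_clipped_at_chromosome_edge(self, toy_genome):
        ps = PeakSet("atac", [GenomicInterval("chr1", 0, 100)])
        acc = build_accessible(ps, toy_genome, extend=150)
        assert acc.regions[0].start == 0
        assert acc.total_size == 250

    def test_empty_input_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            build_accessible(PeakSet("atac", []), toy_genome)

    def test_total_size_vs_bitmap(self, rng, toy_genome):
        ps = random_peakset(rng, toy_genome, 200, name="atac")
        acc = build_accessible(ps, toy_genome, extend=150)
        extended = [
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - 150),
                min(toy_genome.chrom_sizes[iv.chrom], iv.end + 150),
            )
            for iv in ps
        ]
        bitmaps = coverage_bitmap(extended, toy_genome.chrom_sizes)
        assert acc.total_size == sum(int(b.sum()) for b in bitmaps.values())


class TestPairwiseOverlap:
    def test_self_overlap_is_full(self, random_peaks):
        n_ab, _ = pairwise_overlap(random_peaks, random_peaks)
        assert n_ab == len(random_peaks)

    def test_exactly_150_apart_not_overlapping(self):
        a = PeakSet("a", [GenomicInterval("c", 1000, 1100)])  # center 1050
        b = PeakSet("b", [GenomicInterval("c", 1150, 1250)])  # center 1200
        n_ab, _ = pairwise_overlap(a, b, max_center_dist=150)
        assert n_ab == 0

    def test_149_apart_overlapping(self):
        a = PeakSet("a", [GenomicInterval("c", 1000, 1100)])
        b = PeakSet("b", [GenomicInterval("c", 1149, 1249)])  # center 1199
        n_ab, _ = pairwise_overlap(a, b, max_center_dist=150)
        assert n_ab == 1

    def test_asymmetric_counting(self):
        # two A peaks near one B peak: N_AB=2 but N_BA=1
        a = PeakSet("a", [GenomicInterval("c", 1000, 1100), GenomicInterval("c", 1050, 1150)])
        b = PeakSet("b", [GenomicInterval("c", 1020, 1120)])
        assert pairwise_overlap(a, b)[0] == 2
        assert pairwise_overlap(b, a)[0] == 1

    def test_random_vs_all_pairs_oracle(self, rng, toy_genome):
        a = random_peakset(rng, toy_genome, 50, "a")
        b = random_peakset(rng, toy_genome, 50, "b")
        n_ab, pairs = pairwise_overlap(a, b, max_center_dist=150)
        expected_pairs = {
            (i, j)
            for i, iva in enumerate(a)
            for j, ivb in enumerate(b)
            if iva.chrom == ivb.chrom and abs(center(iva) - center(ivb)) < 150
        }
        assert set(pairs) == expected_pairs
        assert n_ab == len({i for i, _ in expected_pairs})


class TestOverlapPvalue:
    def test_zero_overlap_p_one(self):
        t = overlap_pvalue(100, 0, 50, ACCESSIBLE_TOTAL)
        assert t.p_value == 1.0
        assert t.neg_log10_p == 0.0

    def test_p_b_formula(self):
        t = overlap_pvalue(10, 3, 100, ACCESSIBLE_TOTAL)
        assert t.p_b == pytest.approx(300 * 100 / ACCESSIBLE_TOTAL)
        assert t.expected == pytest.approx(10 * t.p_b)

    def test_window_scales_null(self):
        t = overlap_pvalue(10, 3, 100, ACCESSIBLE_TOTAL, max_center_dist=500)
        assert t.p_b == pytest.approx(1000 * 100 / ACCESSIBLE_TOTAL)

    def test_exact_oracle_small(self):
        t = overlap_pvalue(10, 3, 100, ACCESSIBLE_TOTAL)
        oracle = exact_binom_upper_tail(3, 10, 300 * 100 / ACCESSIBLE_TOTAL)
        assert t.p_value == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("n_a,n_ab,n_b", [(1000, 400, 5000), (500, 1, 10), (200, 200, 3000)])
    def test_exact_oracle_larger(self, n_a, n_ab, n_b):
        t = overlap_pvalue(n_a, n_ab, n_b, ACCESSIBLE_TOTAL)
        p_b = min(1.0, 300 * n_b / ACCESSIBLE_TOTAL)
        oracle = exact_binom_upper_tail(n_ab, n_a, p_b)
        if oracle > 1e-300:
            assert t.p_value == pytest.approx(oracle, rel=1e-10)
        assert t.neg_log10_p == pytest.approx(
            exact_binom_neg_log10_upper_tail(n_ab, n_a, p_b), rel=1e-10
        )

    def test_saturated_null(self):
        t = overlap_pvalue(50, 30, 10**9, ACCESSIBLE_TOTAL)
        assert t.p_b == 1.0
        assert t.p_value == 1.0

    def test_p_b_capped_with_warning(self):
        with pytest.warns(UserWarning):
            overlap_pvalue(50, 30, 10**9, ACCESSIBLE_TOTAL)

    def test_n_ab_exceeding_n_a_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(10, 11, 100, ACCESSIBLE_TOTAL)

    def test_no_underflow_at_extreme_significance(self):
        # the reporting scale must stay finite far below float underflow
        t = overlap_pvalue(10_000, 10_000, 100, ACCESSIBLE_TOTAL)
        assert np.isfinite(t.neg_log10_p)
        assert t.neg_log10_p > 1_000

    @given(k=st.integers(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_overlap_count(self, k):
        p1 = overlap_pvalue(50, k, 300, ACCESSIBLE_TOTAL).neg_log10_p
        p2 = overlap_pvalue(50, min(50, k + 1), 300, ACCESSIBLE_TOTAL).neg_log10_p
        assert p2 >= p1


def _cluster(chrom, base, offsets):
    """One peak per factor, centers at base+offset (width 100)."""
    return {
        factor: GenomicInterval(chrom, base + off - 50, base + off + 50)
        for factor, off in offsets.items()
    }


class TestFindHotspots:
    def _sets(self, clusters, factors):
        per_factor = {f: [] for f in factors}
        for cl in clusters:
            for f, iv in cl.items():
                per_factor[f].append(iv)
        return {f: PeakSet(f, ivs) for f, ivs in per_factor.items()}

    def test_four_colocated_factors_one_hotspot(self):
        factors = ["f1", "f2", "f3", "f4"]
        sets = self._sets([_cluster("c", 10_000, {f: i * 10 for i, f in enumerate(factors)})], factors)
        hs = find_hotspots(sets, window=1000)
        assert len(hs) == 1
        assert hs[0].n_factors == 4
        assert set(hs[0].members) == set(factors)

    def test_missing_factor_blocks_at_full_requirement(self):
        factors = ["f1", "f2", "f3", "f4"]
        sets = self._sets(
            [_cluster("c", 10_000, {f: i * 10 for i, f in enumerate(factors[:3])})], factors
        )
        assert find_hotspots(sets, window=1000) == []
        assert len(find_hotspots(sets, window=1000, min_factors=3)) == 1

    def test_hotspot_interval_spans_member_centers(self):
        sets = self._sets([_cluster("c", 10_000, {"f1": 0, "f2": 400})], ["f1", "f2"])
        hs = find_hotspots(sets, window=1000)
        assert hs[0].interval.start == 10_000
        assert hs[0].interval.end == 10_401

    def test_window_is_clique_rule(self):
        # centers 0/600/1200: max-min = 1200 > window, no 3-way group
        sets = self._sets([_cluster("c", 10_000, {"f1": 0, "f2": 600, "f3": 1200})], ["f1", "f2", "f3"])
        assert find_hotspots(sets, window=1000) == []
        assert len(find_hotspots(sets, window=1200)) == 1

    def test_each_peak_in_at_most_one_hotspot(self):
        factors = ["f1", "f2"]
        # one f1 peak between two f2 peaks: only one pairing may be reported
        sets = {
            "f1": PeakSet("f1", [GenomicInterval("c", 10_000, 10_100)]),
            "f2": PeakSet(
                "f2",
                [GenomicInterval("c", 9_800, 9_900), GenomicInterval("c", 10_200, 10_300)],
            ),
        }
        hs = find_hotspots(sets, window=1000)
        assert len(hs) == 1

    def test_toy_vs_exhaustive_enumeration(self, rng):
        # well-separated clusters: greedy must equal full enumeration
        factors = ["f1", "f2", "f3", "f4"]
        n_clusters = 5
        clusters = []
        for ci in range(n_clusters):
            base = 100_000 * (ci + 1)
            present = factors if ci % 2 == 0 else factors[:3]
            offsets = {f: int(rng.integers(0, 400)) for f in present}
            clusters.append(_cluster("c", base, offsets))
        sets = self._sets(clusters, factors)
        hs = find_hotspots(sets, window=1000)

        # oracle: enumerate every one-per-factor combination over all peaks
        pools = [[(f, i, center(iv)) for i, iv in enumerate(sets[f])] for f in factors]
        valid = set()
        for combo in itertools.product(*pools):
            centers = [c for _, _, c in combo]
            if max(centers) - min(centers) <= 1000:
                valid.add(frozenset((f, i) for f, i, _ in combo))
        assert len(hs) == len(valid) == sum(1 for ci in range(n_clusters) if ci % 2 == 0)
        reported = {frozenset(h.members.items()) for h in hs}
        assert reported == valid

    def test_invariant_to_factor_label_permutation(self, rng, toy_genome):
        sets = {
            name: random_peakset(rng, toy_genome, 30, name)
            for name in ["f1", "f2", "f3"]
        }
        hs1 = find_hotspots(sets, window=1000)
        renamed = {"z_" + k: PeakSet("z_" + k, v.intervals) for k, v in sets.items()}
        hs2 = find_hotspots(renamed, window=1000)
        assert [(h.interval, h.n_factors) for h in hs1] == [
            (h.interval, h.n_factors) for h in hs2
        ]
        assert [{("z_" + f, i) for f, i in h.members.items()} for h in hs1] == [
            set(h.members.items()) for h in hs2
        ]

    def test_invariant_to_input_ordering(self, rng, toy_genome):
        sets = {name: random_peakset(rng, toy_genome, 25, name) for name in ["f1", "f2"]}
        shuffled = {}
        for name, ps in sets.items():
            ivs = list(ps.intervals)
            rng.shuffle(ivs)
            shuffled[name] = PeakSet(name, ivs)
        assert find_hotspots(sets, 1000) == find_hotspots(shuffled, 1000)

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            find_hotspots({"f1": PeakSet("f1", [])})


class TestTargetSets:
    def test_ratio_identical_sets(self):
        assert target_set_overlap_ratio({"a", "b"}, {"a", "b"}) == 1.0

    def test_ratio_disjoint(self):
        assert target_set_overlap_ratio({"a"}, {"b"}) == 0.0

    def test_ratio_empty_a_rejected(self):
        with pytest.raises(ValueError):
            target_set_overlap_ratio(set(), {"a"})

    def test_ratio_random_vs_set_oracle(self, rng):
        universe = [f"g{i}" for i in range(300)]
        a = set(rng.choice(universe, 100, replace=False))
        b = set(rng.choice(universe, 100, replace=False))
        assert target_set_overlap_ratio(a, b) == len(a & b) / len(a)

    def test_core_targets_identical_sets(self):
        s = {"a", "b", "c"}
        assert core_targets({"f1": set(s), "f2": set(s)}) == s

    def test_core_targets_one_empty(self):
        assert core_targets({"f1": {"a"}, "f2": set()}) == set()

    def test_core_targets_random_vs_membership_oracle(self, rng):
        universe = [f"g{i}" for i in range(200)]
        sets = {
            f"f{k}": set(rng.choice(universe, 120, replace=False)) for k in range(4)
        }
        expected = {g for g in universe if all(g in s for s in sets.values())}
        assert core_targets(sets) == expected

    def test_core_targets_needs_two_sets(self):
        with pytest.raises(ValueError):
            core_targets({"f1": {"a"}})


class TestScoreByCobinding:
    def _scored(self, centers, scores, name="primary"):
        return PeakSet(
            name,
            [
                GenomicInterval("c", c - 50, c + 50, score=s)
                for c, s in zip(centers, scores)
            ],
        )

    def test_equal_scores_equal_means(self):
        primary = self._scored([1_000, 50_000], [5.0, 5.0])
        others = {"x": PeakSet("x", [GenomicInterval("c", 960, 1060)])}
        parts = score_by_cobinding(primary, others)
        assert {frozenset(), frozenset({"x"})} == set(parts)
        assert all(p["mean"] == 5.0 for p in parts.values())

    def test_planted_bonus_ranks_four_way_highest(self):
        # primary peaks at four sites; co-binding depth 0..3; scores +2 per co-factor
        centers = [10_000, 20_000, 30_000, 40_000]
        scores = [1.0, 3.0, 5.0, 7.0]
        primary = self._scored(centers, scores)
        others = {
            "f2": PeakSet("f2", [GenomicInterval("c", c - 50, c + 50) for c in centers[1:]]),
            "f3": PeakSet("f3", [GenomicInterval("c", c - 50, c + 50) for c in centers[2:]]),
            "f4": PeakSet("f4", [GenomicInterval("c", c - 50, c + 50) for c in centers[3:]]),
        }
        parts = score_by_cobinding(primary, others)
        means = {k: v["mean"] for k, v in parts.items()}
        assert max(means, key=means.get) == frozenset({"f2", "f3", "f4"})

    def test_no_others_single_partition(self):
        primary = self._scored([1_000, 2_000], [1.0, 2.0])
        parts = score_by_cobinding(primary, {})
        assert set(parts) == {frozenset()}
        assert parts[frozenset()]["n"] == 2

    def test_unscored_primary_rejected(self):
        primary = PeakSet("p", [GenomicInterval("c", 0, 100)])
        with pytest.raises(ValueError):
            score_by_cobinding(primary, {})
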