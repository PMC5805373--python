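import numpy as np
import pytest

from cobind.core import GenomeModel, GenomicInterval, PeakSet
from cobind.genes import GeneAnnotation, GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome():
    return GenomeModel({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def toy_genes(toy_genome):
    recs = [
        GeneRecord("g1", "chr1", "+", 100_000, 2_000),
        GeneRecord("g2", "chr1", "-", 400_000, 1_500),
        GeneRecord("g3", "chr1", "+", 800_000, 3_000),
        GeneRecord("g4", "chr2", "-", 250_000, 1_000),
    ]
    return GeneAnnotation(recs)


def random_peakset(rng, genome, n, name="peaks", width=(100, 400)):
    intervals = []
    chroms = list(genome.chrom_sizes)
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        w = int(rng.integers(width[0], width[1] + 1))
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - w))
        intervals.append(GenomicInterval(chrom, start, start + w))
    return PeakSet(name, intervals)


@pytest.fixture
def random_peaks(rng, toy_genome):
    return random_peakset(rng, toy_genome, 50)


def coverage_bitmap(intervals, chrom_sizes):
    """Per-base brute-force coverage oracle."""
    bitmaps = {c: np.zeros(s, dtype=bool) for c, s in chrom_sizes.items()}
    for iv in intervals:
        bitmaps[iv.chrom][iv.start : iv.end] = True
    return bitmaps


def exact_binom_upper_tail(k, n, p):
    """Independent oracle: direct summation of C(n,i) p^i (1-p)^(n-i)."""
    import math

    if k <= 0:
        return 1.0
    return math.fsum(
        math.comb(n, i) * (p**i) * ((1.0 - p) ** (n - i)) for i in range(k, n + 1)
    )


def exact_binom_neg_log10_upper_tail(k, n, p):
    """Exact rational-arithmetic oracle for -log10 P(X >= k), immune to
    underflow: p is taken at its exact binary float value a/2^b, the tail sum
    becomes an integer over a common power-of-two denominator."""
    import math
    from fractions import Fraction

    if k <= 0:
        return 0.0
    pf = Fraction(p)
    num_p, den = pf.numerator, pf.denominator
    num_q = den - num_p
    total = sum(
        math.comb(n, i) * num_p**i * num_q ** (n - i) for i in range(k, n + 1)
    )
    # -log10(total / den^n)
    return n * math.log10(den) - math.log10(total)
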