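"""Spanning/reliable predicates, per-locus tallies and coverage tiers."""

import numpy as np
import pytest

from vntrspan.catalog import GenomicInterval
from vntrspan.coverage import (
    AlignedRead,
    LocusCoverage,
    classify_coverage,
    count_spanning,
    efficiency,
    is_reliable,
    is_spanning,
    normalize_per_million,
    probe_distance,
)

from .conftest import make_locus, make_spanning_read
from .oracles import spanning_counts_oracle


def _bare_read(chrom, start, end, sample="S1", rid="r"):
    return AlignedRead(rid, sample, GenomicInterval(chrom, start, end),
                       "A" * (end - start), [(0, end - start)])


class TestIsSpanning:
    @pytest.mark.parametrize(
        "rstart,rend,expected",
        [
            (990, 1210, True),   # strict containment
            (1000, 1210, False),  # no left flank
            (990, 1200, False),   # no right flank
            (1050, 1150, False),  # read inside locus
        ],
    )
    def test_strict_containment_rule(self, rstart, rend, expected):
        locus = make_locus("chr1", 1000, "ACGTGGACGT", 20)  # [1000, 1200)
        assert is_spanning(_bare_read("chr1", rstart, rend), locus) is expected

    def test_other_chromosome_never_spans(self):
        locus = make_locus("chr1", 1000)
        assert not is_spanning(_bare_read("chr2", 900, 1300), locus)


class TestIsReliable:
    def test_perfect_ten_bp_flanks_pass(self, simple_reference, simple_locus):
        read = make_spanning_read(simple_reference, simple_locus, 10, 10)
        assert is_reliable(read, simple_locus, simple_reference)

    def test_nine_bp_flank_fails(self, simple_reference, simple_locus):
        read = make_spanning_read(simple_reference, simple_locus, 9, 15)
        assert not is_reliable(read, simple_locus, simple_reference)

    def test_one_mismatch_in_ten_bp_flank_fails(self, simple_reference, simple_locus):
        # match rate 9/10 = 0.9 < 0.95 on the left flank
        read = make_spanning_read(simple_reference, simple_locus, 10, 10, mutate_at=(3,))
        assert not is_reliable(read, simple_locus, simple_reference)

    def test_long_flank_tolerates_sparse_mismatches(self, simple_reference, simple_locus):
        # 100 bp window: 2 mismatches -> 98% ≥ 95%
        read = make_spanning_read(simple_reference, simple_locus, 100, 100, mutate_at=(3, 50))
        assert is_reliable(read, simple_locus, simple_reference)

    def test_short_read_mode_checks_only_ten_bp(self, simple_reference, simple_locus):
        # mismatches outside the inner 10 bp are invisible in short-read mode
        read = make_spanning_read(simple_reference, simple_locus, 40, 40,
                                  mutate_at=(5, 10, 15, 20, 25))
        assert not is_reliable(read, simple_locus, simple_reference)
        assert is_reliable(read, simple_locus, simple_reference, short_read_mode=True)

    def test_reliability_implies_spanning_tally(self, simple_reference, simple_locus):
        reads = [
            make_spanning_read(simple_reference, simple_locus, 20, 20, read_id=f"g{i}")
            for i in range(3)
        ] + [
            make_spanning_read(simple_reference, simple_locus, 4, 20, read_id=f"t{i}")
            for i in range(2)
        ]
        per_sample = count_spanning(simple_locus, reads, simple_reference)
        cov = per_sample["S1"]
        assert cov.n_spanning == 5
        assert cov.n_reliable == 3
        assert sum(cov.reliable_by_repeat_count.values()) == cov.n_reliable


class TestCounting:
    def test_zero_reads_at_locus(self, simple_reference, simple_locus):
        assert count_spanning(simple_locus, [], simple_reference) == {}

    def test_agrees_with_all_pairs_oracle(self, rng):
        loci = [make_locus("chr1", int(s), "ACGTGG", 10, locus_id=f"L{i}")
                for i, s in enumerate(range(500, 50500, 500))]
        reads = []
        for i in range(1000):
            start = int(rng.integers(0, 50_000))
            length = int(rng.integers(20, 400))
            reads.append(_bare_read("chr1", start, start + length,
                                    sample=f"S{int(rng.integers(3))}", rid=f"r{i}"))
        expected = spanning_counts_oracle(reads, loci)
        got = {}
        for locus in loci:
            for sid, cov in count_spanning(
                locus, reads, None, with_repeat_counts=False, min_flank=10**9
            ).items():
                got[(locus.locus_id, sid)] = cov.n_spanning
        assert got == expected


class TestProbeDistance:
    def test_overlap_gap_and_missing(self):
        locus = make_locus("chr1", 1000, "ACGTGG", 10)  # [1000, 1060)
        assert probe_distance(locus, [GenomicInterval("chr1", 1030, 1150)]) == 0
        assert probe_distance(locus, [GenomicInterval("chr1", 630, 750)]) == 250
        assert probe_distance(locus, [GenomicInterval("chr2", 0, 120)]) is None
        assert probe_distance(locus, []) is None
        # nearest of several
        probes = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1100, 1220)]
        assert probe_distance(locus, probes) == 40


def _covs(counts, locus_id="L"):
    return [LocusCoverage(locus_id, f"S{i}", n_spanning=c) for i, c in enumerate(counts)]


class TestClassification:
    @pytest.mark.parametrize(
        "counts,tier,variance",
        [
            ([20, 20, 20, 20], "well_covered", 0.0),
            ([100, 80, 70, 90], "high", 0.0),  # all project to 30
            ([0, 0, 0, 0], "uncovered", 0.0),
            ([5, 5, 5, 5], "low", 0.0),
        ],
    )
    def test_tiers_and_projected_variance(self, counts, tier, variance):
        c = classify_coverage(_covs(counts))
        assert c.tier == tier
        assert c.cross_sample_variance == pytest.approx(variance)

    def test_even_sample_median_is_midpoint(self):
        c = classify_coverage(_covs([14, 16, 0, 40]))
        assert c.median_spanning == 15.0
        assert c.tier == "well_covered"

    def test_permutation_invariant(self, rng):
        counts = list(rng.integers(0, 100, size=9))
        base = classify_coverage(_covs(counts))
        perm = classify_coverage(_covs(list(rng.permutation(counts))))
        assert (base.median_spanning, base.tier, base.cross_sample_variance) == (
            perm.median_spanning, perm.tier, perm.cross_sample_variance)

    def test_empty_sample_list_errors(self):
        with pytest.raises(ValueError):
            classify_coverage([])


class TestNormalisationAndEfficiency:
    @pytest.mark.parametrize("n,total,expected", [(15, 1_000_000, 15.0), (0, 5, 0.0), (4, 2_000_000, 2.0)])
    def test_per_million(self, n, total, expected):
        assert normalize_per_million(LocusCoverage("L", "S", n_spanning=n), total) == expected

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            normalize_per_million(LocusCoverage("L", "S", n_spanning=1), 0)

    def test_planted_overlap_fraction(self):
        locus = make_locus("chr1", 10_000, "ACGTGG", 10)
        on = [_bare_read("chr1", 9_990, 10_030, rid=f"on{i}") for i in range(36)]
        off = [_bare_read("chr1", 100 + 60 * i, 150 + 60 * i, rid=f"off{i}") for i in range(64)]
        assert efficiency(on + off, [locus]) == pytest.approx(0.36)
        assert efficiency(on, [locus]) == 1.0
        assert efficiency(off, [locus]) == 0.0
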