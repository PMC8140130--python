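"""Promoter windows, merged DMRs, ceDMR classification and gene assignment."""

import numpy as np
import pytest

from dmrcompare.genome_model import GeneModel, GenomicInterval, IntervalSet, SegmentationStack
from dmrcompare.regulatory import (
    assign_to_gene,
    classify_ce_dmrs,
    define_promoters,
    geneset_regulatory_overlap,
    merge_consecutive,
    pathway_regulatory_table,
    regulatory_breakdown,
)


def gene(gid, chrom, strand, start, end):
    return GeneModel(gid, chrom, strand, GenomicInterval(chrom, start, end))


class TestPromoters:
    def test_plus_strand_core(self):
        g = gene("G1", "chr1", "+", 10_000, 20_000)
        (iv, gid), = define_promoters([g], "core_1kb").intervals
        assert (iv.start, iv.end, gid) == (9_500, 10_500, "G1")

    def test_minus_strand_extended_reaches_rightward(self):
        g = gene("G1", "chr1", "-", 2_000, 10_000)  # TSS at 10_000
        (iv, _), = define_promoters([g], "extended_2p5kb").intervals
        assert (iv.start, iv.end) == (9_500, 12_000)

    def test_clipped_at_chromosome_start(self):
        g = gene("G1", "chr1", "+", 200, 5_000)
        (iv, _), = define_promoters([g], "core_1kb").intervals
        assert (iv.start, iv.end) == (0, 700)

    def test_all_transcripts_represented(self):
        gs = [gene("G1", "chr1", "+", 10_000, 20_000),
              gene("G1", "chr1", "+", 12_000, 20_000)]
        assert len(define_promoters(gs, "core_1kb").intervals) == 2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            define_promoters([], "huge")


class TestMergeConsecutive:
    def test_adjacent_bins_merge(self):
        merged = merge_consecutive([("chr1", 1000), ("chr1", 1500)])
        assert merged == [GenomicInterval("chr1", 1000, 2000)]

    def test_gap_stays_split(self):
        merged = merge_consecutive([("chr1", 1000), ("chr1", 2000)])
        assert len(merged) == 2

    def test_idempotent_and_bp_preserving(self, rng):
        bins = sorted({("chr1", 500 * int(i)) for i in rng.choice(200, size=80, replace=False)})
        merged = merge_consecutive(bins)
        assert sum(iv.width for iv in merged) == 500 * len(bins)
        again = IntervalSet.from_intervals(merged).intervals()
        assert again == merged

    def test_opposite_directions_merged_separately(self):
        # caller contract: one direction per call; adjacent bins of opposite
        # direction stay distinct because they arrive in different calls
        hyper = merge_consecutive([("chr1", 1000)])
        hypo = merge_consecutive([("chr1", 1500)])
        assert hyper[0].end == hypo[0].start  # abutting but separate intervals


def enhancer_stack():
    return SegmentationStack(
        model="18-state",
        epigenomes={
            "E00": [
                (GenomicInterval("chr1", 0, 2_000), "1_TssA"),
                (GenomicInterval("chr1", 20_000, 21_000), "9_EnhA1"),
                (GenomicInterval("chr1", 40_000, 41_000), "10_EnhA2"),
            ],
            "E01": [(GenomicInterval("chr1", 60_000, 61_000), "9_EnhA1")],
        },
    )


class TestCeDMRs:
    def test_discard_then_require_filter(self):
        from dmrcompare.regulatory import active_enhancer_union

        genes = [gene("G1", "chr1", "+", 10_000, 15_000)]  # promoter ~[8000,10500)
        promoters = define_promoters(genes, "extended_2p5kb")
        union = active_enhancer_union(enhancer_stack())
        merged = [
            GenomicInterval("chr1", 9_000, 9_500),     # inside promoter -> discarded
            GenomicInterval("chr1", 20_999, 21_500),   # 1 bp enhancer overlap -> kept
            GenomicInterval("chr1", 30_000, 30_500),   # neither -> excluded
            GenomicInterval("chr1", 60_200, 60_700),   # E01 enhancer -> kept
        ]
        ce = classify_ce_dmrs(merged, promoters, union, direction="hyper")
        assert [d.start for d in ce.dmrs] == [20_999, 60_200]
        assert ce.n_promoter_discarded == 1 and ce.n_input == 4

    def test_active_enhancer_union_requires_18_state(self):
        from dmrcompare.regulatory import active_enhancer_union

        stack15 = SegmentationStack(
            model="15-state",
            epigenomes={"F00": [(GenomicInterval("chr1", 0, 1000), "7_Enh")]},
        )
        with pytest.raises(ValueError):
            active_enhancer_union(stack15)


class TestRegulatoryBreakdown:
    def test_hand_classified_fixture(self):
        promoters = IntervalSet.from_intervals([GenomicInterval("chr1", 0, 5_000)])
        enhancers = IntervalSet.from_intervals([GenomicInterval("chr1", 4_000, 9_000)])
        dmrs = (
            [GenomicInterval("chr1", 4_200, 4_700)] * 2      # both
            + [GenomicInterval("chr1", 1_000, 1_500)] * 3    # promoter only
            + [GenomicInterval("chr1", 8_000, 8_500)] * 4    # enhancer only
            + [GenomicInterval("chr1", 20_000, 20_500)]      # neither
        )
        pct = regulatory_breakdown(dmrs, promoters, enhancers)
        assert pct == {"both": 20.0, "promoter_only": 30.0,
                       "enhancer_only": 40.0, "neither": 10.0}
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_empty_enhancer_union(self):
        promoters = IntervalSet.from_intervals([GenomicInterval("chr1", 0, 5_000)])
        pct = regulatory_breakdown(
            [GenomicInterval("chr1", 1_000, 1_500)], promoters, IntervalSet({})
        )
        assert pct["promoter_only"] == 100.0
        assert pct["both"] == 0.0 and pct["enhancer_only"] == 0.0


class TestAssignToGene:
    def test_contained_tss_distance_zero(self):
        genes = [gene("G1", "chr1", "+", 10_100, 15_000)]
        res = assign_to_gene([GenomicInterval("chr1", 10_000, 10_500)], genes)
        assert res.assignments["chr1:10000-10500"] == ("G1", 0)

    def test_beyond_max_distance_unassigned(self):
        genes = [gene("G1", "chr1", "+", 600_000, 650_000)]
        region = GenomicInterval("chr1", 0, 500)  # edge 499 -> TSS 600000: 500,001 bp? no:
        # distance = 600000 - 499 = 599501 > 500000 -> unassigned
        res = assign_to_gene([region], genes)
        assert res.assignments == {} and res.unassigned == ["chr1:0-500"]

    def test_exactly_at_threshold_assigned(self):
        genes = [gene("G1", "chr1", "+", 500_499, 600_000)]
        # TSS - (end-1) = 500499 - 499 = 500000 -> assigned (rule is > 500000)
        res = assign_to_gene([GenomicInterval("chr1", 0, 500)], genes)
        assert res.assignments["chr1:0-500"] == ("G1", 500_000)

    def test_tie_broken_lexicographically(self, caplog):
        genes = [gene("GB", "chr1", "+", 2_000, 5_000),
                 gene("GA", "chr1", "-", 1_000, 1_400)]  # TSS 1400 and 2000
        region = GenomicInterval("chr1", 1_500, 1_901)  # edges 1500/1900, both 100 away? no
        # distances: GA tss 1400 -> 1400-1500 = -100; GB tss 2000 -> 2000-1900 = 100
        with caplog.at_level("WARNING"):
            res = assign_to_gene([region], genes)
        assert res.assignments["chr1:1500-1901"][0] == "GA"

    def test_matches_brute_force_all_pairs(self, rng):
        genes = [
            gene(f"G{i:02d}", "chr1", "+" if i % 2 else "-",
                 int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(0, 2_000_000, size=20))
        ]
        regions = []
        for s in rng.integers(0, 2_000_000, size=50):
            regions.append(GenomicInterval("chr1", int(s), int(s) + 500))
        res = assign_to_gene(regions, genes)
        for r in regions:
            label = f"chr1:{r.start}-{r.end}"
            # brute force: all-pairs minimum edge distance
            def dist(g):
                if r.start <= g.tss < r.end:
                    return 0
                return min(abs(g.tss - r.start), abs(g.tss - (r.end - 1)))
            best = min((dist(g), g.gene_id) for g in genes)
            if best[0] > 500_000:
                assert label in res.unassigned
            else:
                assert res.assignments[label][0] == best[1]
                assert abs(res.assignments[label][1]) == best[0]

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            assign_to_gene([], [])


class TestGenesetOverlap:
    def test_disjoint_sets_p_one(self):
        t = geneset_regulatory_overlap(
            {"A": {"g1", "g2"}, "B": {"g3"}}, [f"g{i}" for i in range(1, 21)]
        )
        assert t.observed == 0 and t.test.log10_p == 0.0

    def test_exhaustive_oracle_universe_20(self):
        import math
        from fractions import Fraction

        universe = [f"g{i}" for i in range(20)]
        set_a = set(universe[:5])
        set_b = set(universe[2:6])  # intersection 3
        t = geneset_regulatory_overlap({"A": set_a, "B": set_b}, universe)
        exact = sum(
            Fraction(math.comb(5, x) * math.comb(15, 4 - x), math.comb(20, 4))
            for x in range(3, 5)
        )
        assert 10 ** t.test.log10_p == pytest.approx(float(exact), rel=1e-12)

    def test_identical_sets_maximal_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        s = set(universe[:6])
        t = geneset_regulatory_overlap({"A": s, "B": set(s)}, universe)
        assert t.observed == 6
        # minimal p among all possible observed values
        smaller = geneset_regulatory_overlap({"A": s, "B": set(universe[1:7])}, universe)
        assert t.test.log10_p <= smaller.test.log10_p

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            geneset_regulatory_overlap({"A": {"gX"}, "B": set()}, ["g1"])


class TestPathwayTable:
    def test_flags(self):
        genes = [gene("APO1", "chr1", "+", 50_000, 60_000),
                 gene("APO2", "chr1", "+", 200_000, 210_000),
                 gene("FAR", "chr2", "+", 5_000, 9_000)]
        promoters = define_promoters(genes, "extended_2p5kb")
        dmrs = [GenomicInterval("chr1", 49_000, 49_500),     # in APO1 promoter
                GenomicInterval("chr1", 150_000, 150_500)]   # inside an enhancer
        enhancers = [GenomicInterval("chr1", 149_800, 150_700)]  # nearest TSS: APO2
        table = pathway_regulatory_table(
            ["APO1", "APO2", "FAR", "UNKNOWN"], dmrs, promoters, enhancers, genes
        )
        assert table["APO1"] == {"promoter_hit": True, "enhancer_hit": False}
        assert table["APO2"] == {"promoter_hit": False, "enhancer_hit": True}
        assert table["FAR"] == {"promoter_hit": False, "enhancer_hit": False}
        assert "UNKNOWN" not in table

    def test_promoter_overlapping_enhancers_removed_before_assignment(self):
        genes = [gene("G1", "chr1", "+", 50_000, 60_000)]
        promoters = define_promoters(genes, "extended_2p5kb")
        # enhancer inside the promoter window: must NOT produce an enhancer hit
        enhancers = [GenomicInterval("chr1", 49_000, 49_600)]
        dmrs = [GenomicInterval("chr1", 49_000, 49_500)]
        table = pathway_regulatory_table(["G1"], dmrs, promoters, enhancers, genes)
        assert table["G1"]["enhancer_hit"] is False
        assert table["G1"]["promoter_hit"] is True
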