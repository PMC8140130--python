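"""Coverage-fraction enrichment, state presence and peak occupancy."""

import numpy as np
import pytest

from dmrcompare.enrichment import (
    feature_enrichment,
    chromhmm_enrichment,
    group_fraction_test,
    peak_occupancy,
    signal_enrichment,
    state_presence,
)
from dmrcompare.genome_model import (
    BackgroundSet,
    GenomicInterval,
    IntervalSet,
    SegmentationStack,
)


def bg_of_bins(*keys):
    return BackgroundSet(bins=tuple(keys))


class TestFeatureEnrichment:
    def test_hand_example_half_promoter(self):
        dmrs = IntervalSet.from_intervals([GenomicInterval("chr1", 1000, 1500)])
        promoter = IntervalSet.from_intervals([GenomicInterval("chr1", 0, 1250)])
        bg = bg_of_bins(*[("chr1", 500 * i) for i in range(10)])  # promoter covers 1250 bp
        (res,) = feature_enrichment(dmrs, {"promoter": promoter}, bg)
        assert res.dmr_fraction == pytest.approx(0.5)
        assert res.background_fraction == pytest.approx(0.25)
        assert res.enrichment == pytest.approx(2.0)

    def test_background_against_itself_is_one(self):
        bg = bg_of_bins(("chr1", 0), ("chr1", 1000), ("chr2", 500))
        features = {
            "half": IntervalSet.from_intervals([GenomicInterval("chr1", 0, 1500)]),
            "genome": IntervalSet.from_intervals([GenomicInterval("chr1", 0, 10_000),
                                                  GenomicInterval("chr2", 0, 10_000)]),
        }
        for res in feature_enrichment(bg.interval_set(), features, bg):
            assert res.enrichment == pytest.approx(1.0)

    def test_zero_background_overlap_reported_undefined(self):
        dmrs = IntervalSet.from_intervals([GenomicInterval("chr1", 0, 500)])
        bg = bg_of_bins(("chr1", 0))
        feat = {"elsewhere": IntervalSet.from_intervals([GenomicInterval("chr2", 0, 100)])}
        (res,) = feature_enrichment(dmrs, feat, bg)
        assert res.enrichment is None

    def test_empty_dmr_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            feature_enrichment(IntervalSet({}), {}, bg_of_bins(("chr1", 0)))

    def test_fractions_may_sum_above_one(self):
        # overlapping feature categories are not mutually exclusive
        dmrs = IntervalSet.from_intervals([GenomicInterval("chr1", 0, 500)])
        bg = bg_of_bins(("chr1", 0), ("chr1", 500))
        feats = {
            "a": IntervalSet.from_intervals([GenomicInterval("chr1", 0, 1000)]),
            "b": IntervalSet.from_intervals([GenomicInterval("chr1", 0, 600)]),
        }
        results = feature_enrichment(dmrs, feats, bg)
        assert sum(r.dmr_fraction for r in results) > 1.0


def toy_stack():
    """Two epigenomes, three states, 10 kb on one chromosome."""
    segs = {
        "E00": [
            (GenomicInterval("chr1", 0, 3000), "1_TssA"),
            (GenomicInterval("chr1", 3000, 7000), "9_EnhA1"),
            (GenomicInterval("chr1", 7000, 10_000), "18_Quies"),
        ],
        "E01": [
            (GenomicInterval("chr1", 0, 5000), "18_Quies"),
            (GenomicInterval("chr1", 5000, 10_000), "9_EnhA1"),
        ],
    }
    return SegmentationStack(model="18-state", epigenomes=segs)


class TestChromhmmEnrichment:
    def test_single_state_segmentation_enrichment_one(self):
        stack = SegmentationStack(
            model="18-state",
            epigenomes={"E00": [(GenomicInterval("chr1", 0, 10_000), "5_Tx")]},
        )
        dmrs = IntervalSet.from_bins([("chr1", 1000)])
        bg = bg_of_bins(*[("chr1", 500 * i) for i in range(20)])
        results = chromhmm_enrichment(dmrs, stack, bg, states=["5_Tx"])
        assert results[0].enrichment == pytest.approx(1.0)

    def test_matches_per_nucleotide_brute_force(self):
        stack = toy_stack()
        dmr_bins = [("chr1", 2500), ("chr1", 5000), ("chr1", 6000)]
        dmrs = IntervalSet.from_bins(dmr_bins)
        bg_keys = [("chr1", 500 * i) for i in range(20)]
        bg = bg_of_bins(*bg_keys)
        results = chromhmm_enrichment(dmrs, stack, bg)
        by_key = {(r.epigenome_id, r.feature_id): r for r in results}

        # brute force per nucleotide
        for eid, segs in stack.epigenomes.items():
            state_of = {}
            for iv, st in segs:
                for p in range(iv.start, iv.end):
                    state_of[p] = st
            dmr_nt = [p for c, s in dmr_bins for p in range(s, s + 500)]
            bg_nt = [p for c, s in bg_keys for p in range(s, s + 500)]
            for state in {"1_TssA", "9_EnhA1", "18_Quies"}:
                dfrac = sum(state_of.get(p) == state for p in dmr_nt) / len(dmr_nt)
                bfrac = sum(state_of.get(p) == state for p in bg_nt) / len(bg_nt)
                r = by_key[(eid, state)]
                assert r.dmr_fraction == pytest.approx(dfrac)
                assert r.background_fraction == pytest.approx(bfrac)

    def test_state_absent_from_epigenome_zero_fraction(self):
        stack = toy_stack()
        dmrs = IntervalSet.from_bins([("chr1", 0)])
        bg = bg_of_bins(*[("chr1", 500 * i) for i in range(20)])
        by_key = {
            (r.epigenome_id, r.feature_id): r
            for r in chromhmm_enrichment(dmrs, stack, bg, states=["1_TssA"])
        }
        assert by_key[("E01", "1_TssA")].dmr_fraction == 0.0


class TestSignalEnrichment:
    def test_uniform_signal_ratio_one(self):
        bg = bg_of_bins(("chr1", 0), ("chr1", 500), ("chr1", 1000))
        dmrs = IntervalSet.from_bins([("chr1", 500)])
        track = [GenomicInterval("chr1", 0, 1500, value=2.5)]
        assert signal_enrichment(dmrs, track, bg) == pytest.approx(1.0)

    def test_signal_only_inside_dmrs(self):
        # 3 background bins, 1 DMR bin carrying all signal at level 1:
        # DMR mean 1, background mean 1/3 -> ratio 3 (= bg_bp / dmr_bp)
        bg = bg_of_bins(("chr1", 0), ("chr1", 500), ("chr1", 1000))
        dmrs = IntervalSet.from_bins([("chr1", 500)])
        track = [GenomicInterval("chr1", 500, 1000, value=1.0)]
        assert signal_enrichment(dmrs, track, bg) == pytest.approx(3.0)

    def test_empty_track_undefined(self):
        bg = bg_of_bins(("chr1", 0))
        dmrs = IntervalSet.from_bins([("chr1", 0)])
        assert signal_enrichment(dmrs, [], bg) is None

    def test_negative_signal_rejected(self):
        bg = bg_of_bins(("chr1", 0))
        dmrs = IntervalSet.from_bins([("chr1", 0)])
        with pytest.raises(ValueError, match=">= 0"):
            signal_enrichment(dmrs, [GenomicInterval("chr1", 0, 100, value=-1.0)], bg)


class TestStatePresence:
    def test_one_bp_overlap_counts(self):
        stack = toy_stack()
        dmrs = [GenomicInterval("chr1", 2999, 3500)]  # 1 bp of 1_TssA in E00
        pm = state_presence(dmrs, stack, ["1_TssA"])
        assert pm.matrix[0, pm.epigenome_ids.index("E00")] == 1
        assert pm.matrix[0, pm.epigenome_ids.index("E01")] == 0

    def test_all_inside_state_all_ones(self):
        stack = toy_stack()
        dmrs = [GenomicInterval("chr1", 5500, 6000), GenomicInterval("chr1", 6000, 6500)]
        pm = state_presence(dmrs, stack, ["9_EnhA1"])
        assert pm.matrix.all()
        assert all(v == 1.0 for v in pm.column_fractions.values())

    def test_invariant_to_splitting_state_intervals(self):
        split = {
            "E00": [
                (GenomicInterval("chr1", 0, 1500), "9_EnhA1"),
                (GenomicInterval("chr1", 1500, 3000), "9_EnhA1"),
            ]
        }
        whole = {"E00": [(GenomicInterval("chr1", 0, 3000), "9_EnhA1")]}
        dmrs = [GenomicInterval("chr1", 1000, 2000), GenomicInterval("chr1", 4000, 4500)]
        pm_a = state_presence(dmrs, SegmentationStack("18-state", split), ["9_EnhA1"])
        pm_b = state_presence(dmrs, SegmentationStack("18-state", whole), ["9_EnhA1"])
        assert (pm_a.matrix == pm_b.matrix).all()

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            state_presence([], toy_stack(), ["7_Enh"])

    def test_matches_brute_force_scan(self):
        stack = toy_stack()
        dmrs = [GenomicInterval("chr1", 500 * i, 500 * i + 500) for i in range(20)]
        pm = state_presence(dmrs, stack, ["9_EnhA1", "1_TssA"])
        for i, d in enumerate(dmrs):
            for j, eid in enumerate(pm.epigenome_ids):
                expect = any(
                    st in ("9_EnhA1", "1_TssA") and iv.start < d.end and d.start < iv.end
                    for iv, st in stack.epigenomes[eid]
                )
                assert bool(pm.matrix[i, j]) == expect


class TestPeakOccupancy:
    def test_identity_peaks_full_occupancy_both_directions(self):
        dmrs = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 1000, 1500)]
        peaks = {"adult1": IntervalSet.from_intervals(dmrs)}
        pm, reciprocal = peak_occupancy(dmrs, peaks, {"adult": ["adult1"]})
        assert pm.matrix.all()
        assert reciprocal["adult"] == pytest.approx(1.0)

    def test_group_union_of_disjoint_members(self):
        dmrs = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 1000, 1500)]
        peaks = {
            "a": IntervalSet.from_intervals([GenomicInterval("chr1", 0, 500)]),
            "b": IntervalSet.from_intervals([GenomicInterval("chr1", 1000, 1500)]),
        }
        pm, _ = peak_occupancy(dmrs, peaks, {"grp": ["a", "b"]})
        assert pm.matrix.all()  # union covers both DMRs

    def test_no_peaks_zero_occupancy(self):
        dmrs = [GenomicInterval("chr1", 0, 500)]
        peaks = {"a": IntervalSet.from_intervals([GenomicInterval("chr2", 0, 100)])}
        pm, reciprocal = peak_occupancy(dmrs, peaks, {"grp": ["a"]})
        assert not pm.matrix.any()
        assert reciprocal["grp"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peak_occupancy([], {}, {"grp": []})


class TestGroupFractionTest:
    def test_identical_lists_statistic_zero(self):
        stat, p = group_fraction_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert stat == 0.0 and p == 1.0

    def test_separated_groups_significant(self, rng):
        a = [0.9 + rng.normal(0, 1e-3) for _ in range(3)]
        b = [0.1 + rng.normal(0, 1e-3) for _ in range(3)]
        _, p = group_fraction_test(a, b)
        assert p < 1e-3

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            group_fraction_test([0.5], [0.5, 0.6])

    def test_permutation_oracle_agreement(self, rng):
        from scipy.stats import permutation_test

        a = list(rng.normal(0.62, 0.08, size=7))  # adult-like group
        b = list(rng.normal(0.50, 0.08, size=6))  # fetal-like group
        stat, p = group_fraction_test(a, b)
        perm = permutation_test(
            (a, b),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            n_resamples=10**5,
            alternative="two-sided",
            rng=np.random.default_rng(7),
        )
        assert p == pytest.approx(perm.pvalue, abs=0.02)
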