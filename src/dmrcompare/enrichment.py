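"""Nucleotide-level enrichment of DMR groups over genomic features.

The central statistic is a ratio of coverage fractions: the fraction of DMR
nucleotides falling inside a feature, divided by the fraction of background
nucleotides falling inside the same feature.  Feature categories are not
mutually exclusive, so fractions across features may sum above 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_model import BackgroundSet, GenomicInterval, IntervalSet, SegmentationStack

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    group_id: str
    feature_id: str
    dmr_fraction: float
    background_fraction: float
    enrichment: Optional[float]  # None when background_fraction == 0
    epigenome_id: Optional[str] = None


def feature_enrichment(
    dmrs: IntervalSet,
    features: Mapping[str, IntervalSet],
    background: BackgroundSet,
    group_id: str = "dmrs",
) -> List[EnrichmentResult]:
    """Coverage-fraction enrichment of a DMR group over named feature sets."""
    if not dmrs:
        raise ValueError("empty DMR set")
    dmr_bp = dmrs.total_bp
    bg = background.interval_set()
    bg_bp = bg.total_bp
    out = []
    for fid, fset in features.items():
        dfrac = dmrs.overlap_bp(fset) / dmr_bp
        bfrac = bg.overlap_bp(fset) / bg_bp
        enr = dfrac / bfrac if bfrac > 0 else None
        if enr is None:
            logger.warning("feature %s has zero background overlap; enrichment undefined", fid)
        out.append(EnrichmentResult(group_id, fid, dfrac, bfrac, enr))
    return out


def chromhmm_enrichment(
    dmrs: IntervalSet,
    stack: SegmentationStack,
    background: BackgroundSet,
    group_id: str = "dmrs",
    states: Optional[Sequence[str]] = None,
) -> List[EnrichmentResult]:
    """One coverage-fraction enrichment per (chromatin state, epigenome)."""
    state_list = list(states) if states is not None else list(stack.state_vocabulary)
    out = []
    for eid in stack.epigenome_ids:
        features = {s: stack.state_intervals(eid, [s]) for s in state_list}
        for res in feature_enrichment(dmrs, features, background, group_id):
            res.epigenome_id = eid
            out.append(res)
    return out


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group_id,
                "feature": r.feature_id,
                "epigenome": r.epigenome_id,
                "dmr_fraction": r.dmr_fraction,
                "background_fraction": r.background_fraction,
                "enrichment": np.nan if r.enrichment is None else r.enrichment,
            }
            for r in results
        ]
    )


def signal_enrichment(
    dmrs: IntervalSet,
    signal: Sequence[GenomicInterval],
    background: BackgroundSet,
) -> Optional[float]:
    """Mean per-nucleotide signal over DMR bp divided by the background mean.

    Nucleotides not covered by the track contribute 0.  Returns None when the
    background mean is 0 (undefined ratio).
    """
    def _mass_over(region: IntervalSet) -> float:
        total = 0.0
        for iv in signal:
            if iv.value is None:
                raise ValueError("signal track interval without a value")
            if iv.value < 0:
                raise ValueError("signal values must be >= 0")
            bp = region.overlap_bp_interval(iv.chrom, iv.start, iv.end)
            total += bp * iv.value
        return total

    dmr_bp = dmrs.total_bp
    bg = background.interval_set()
    mean_dmr = _mass_over(dmrs) / dmr_bp
    mean_bg = _mass_over(bg) / bg.total_bp
    if mean_bg == 0:
        logger.warning("zero background signal mean; enrichment undefined")
        return None
    return mean_dmr / mean_bg


@dataclass
class PresenceMatrix:
    """DMR x epigenome binary presence with per-epigenome column fractions."""

    dmr_ids: List[str]
    epigenome_ids: List[str]
    matrix: np.ndarray  # shape (n_dmrs, n_epigenomes), entries {0, 1}

    @property
    def column_fractions(self) -> Dict[str, float]:
        means = self.matrix.mean(axis=0) if len(self.dmr_ids) else np.zeros(len(self.epigenome_ids))
        return dict(zip(self.epigenome_ids, means.astype(float)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.dmr_ids, columns=self.epigenome_ids)


def _dmr_label(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def state_presence(
    dmrs: Sequence[GenomicInterval],
    stack: SegmentationStack,
    target_states: Sequence[str],
    min_overlap_bp: int = 1,
) -> PresenceMatrix:
    """Per (DMR, epigenome): 1 iff the DMR overlaps >= min_overlap_bp of any
    target state in that epigenome."""
    unknown = set(target_states) - set(stack.state_vocabulary)
    if unknown:
        raise ValueError(f"states {sorted(unknown)} not in {stack.model} vocabulary")
    eids = stack.epigenome_ids
    mat = np.zeros((len(dmrs), len(eids)), dtype=np.int8)
    for j, eid in enumerate(eids):
        target = stack.state_intervals(eid, target_states)
        for i, d in enumerate(dmrs):
            if target.overlap_bp_interval(d.chrom, d.start, d.end) >= min_overlap_bp:
                mat[i, j] = 1
    return PresenceMatrix([_dmr_label(d) for d in dmrs], list(eids), mat)


def peak_occupancy(
    dmr_subset: Sequence[GenomicInterval],
    peak_sets: Mapping[str, IntervalSet],
    merge_groups: Mapping[str, Sequence[str]],
    min_overlap_bp: int = 1,
) -> Tuple[PresenceMatrix, Dict[str, float]]:
    """Presence of merged peak groups in a DMR subset, plus the reciprocal
    fraction of each group's peak bp falling inside the DMR subset."""
    listed = [e for members in merge_groups.values() for e in members]
    if len(listed) != len(set(listed)):
        raise ValueError("merge groups must not share epigenomes")
    group_ids = sorted(merge_groups)
    merged: Dict[str, IntervalSet] = {}
    for gid in group_ids:
        members = merge_groups[gid]
        if not members:
            raise ValueError(f"empty merge group {gid!r}")
        acc = peak_sets[members[0]]
        for m in members[1:]:
            acc = acc.union(peak_sets[m])
        merged[gid] = acc

    mat = np.zeros((len(dmr_subset), len(group_ids)), dtype=np.int8)
    for j, gid in enumerate(group_ids):
        for i, d in enumerate(dmr_subset):
            if merged[gid].overlap_bp_interval(d.chrom, d.start, d.end) >= min_overlap_bp:
                mat[i, j] = 1
    presence = PresenceMatrix([_dmr_label(d) for d in dmr_subset], group_ids, mat)

    dmr_set = IntervalSet.from_intervals(dmr_subset)
    reciprocal = {
        gid: (merged[gid].overlap_bp(dmr_set) / merged[gid].total_bp)
        if merged[gid].total_bp
        else 0.0
        for gid in group_ids
    }
    return presence, reciprocal


def group_fraction_test(
    fractions_a: Sequence[float],
    fractions_b: Sequence[float],
    equal_var: bool = False,
) -> Tuple[float, float]:
    """Two-sample t-test (Welch by default) on per-epigenome presence fractions."""
    if len(fractions_a) < 2 or len(fractions_b) < 2:
        raise ValueError("each group needs >= 2 epigenomes")
    res = sps.ttest_ind(fractions_a, fractions_b, equal_var=equal_var)
    stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(stat):  # both groups constant and equal
        return 0.0, 1.0
    return stat, p
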