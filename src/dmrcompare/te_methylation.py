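"""Transposable-element DMR overlap, subfamily enrichment and copy methylation.

Subfamily enrichment compares the rate at which DMRs contain a subfamily's
copies against the subfamily's genome-wide window footprint:

    E_s = (n_TE / n_DMR) / (N_TE / N_all)

where n_TE counts DMRs containing >= 1 copy of the subfamily, n_DMR the DMRs
in the group, N_TE the 500-bp genome windows overlapped by the subfamily and
N_all all 500-bp genome windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .genome_model import (
    ACTIVE_ENHANCER_STATES_18,
    TSS_STATES_18,
    BIN_SIZE,
    Bin,
    GenomicInterval,
    IntervalSet,
    SegmentationStack,
    TECopy,
)
from .regulatory import PromoterSet

logger = logging.getLogger(__name__)


@dataclass
class TEOverlapResult:
    records: List[Tuple[str, str, int]]  # (dmr label, subfamily, overlap bp)
    fraction_with_te: float
    te_sub_regions: List[GenomicInterval]  # DMR∩TE pieces, for the cascade


def _label(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def te_dmr_overlap(
    dmrs: Sequence[GenomicInterval],
    te_table: Sequence[TECopy],
    min_overlap_bp: int = 1,
) -> TEOverlapResult:
    """Which DMRs contain TEs (>= 1 bp overlap), and the overlapped pieces."""
    by_sub: Dict[str, IntervalSet] = {}
    groups: Dict[str, List[GenomicInterval]] = {}
    for t in te_table:
        groups.setdefault(t.subfamily, []).append(t.interval)
    by_sub = {s: IntervalSet.from_intervals(ivs) for s, ivs in groups.items()}

    all_te = IntervalSet.from_intervals(t.interval for t in te_table)
    records: List[Tuple[str, str, int]] = []
    with_te: Set[str] = set()
    pieces: List[GenomicInterval] = []
    for d in dmrs:
        hit = False
        for sub, ivset in by_sub.items():
            bp = ivset.overlap_bp_interval(d.chrom, d.start, d.end)
            if bp >= min_overlap_bp:
                records.append((_label(d), sub, bp))
                hit = True
        if hit:
            with_te.add(_label(d))
            d_set = IntervalSet.from_intervals([d])
            pieces.extend(d_set.intersect(all_te).intervals())
    frac = len(with_te) / len(dmrs) if dmrs else 0.0
    return TEOverlapResult(records=records, fraction_with_te=frac, te_sub_regions=pieces)


CASCADE_TIERS = ("genic_promoter", "state_TSS", "state_active_enhancer", "other")


def te_regulatory_cascade(
    te_dmr_regions: Sequence[GenomicInterval],
    promoters_extended: PromoterSet,
    stack: SegmentationStack,
) -> Dict[str, float]:
    """Strictly sequential bp assignment of DMR-overlapped TE pieces.

    First matching tier wins: gene-model 2.5-kb promoter, then TSS-like
    states (1-4) in >= 1 epigenome, then active-enhancer states (9/10) in
    >= 1 epigenome, then other.  Tier bp percentages sum to 100.
    """
    regions = IntervalSet.from_intervals(te_dmr_regions)
    total = regions.total_bp
    if total == 0:
        return {t: 0.0 for t in CASCADE_TIERS}

    tiers = {
        "genic_promoter": promoters_extended.interval_set(),
        "state_TSS": stack.state_union(TSS_STATES_18),
        "state_active_enhancer": stack.state_union(ACTIVE_ENHANCER_STATES_18),
    }
    out: Dict[str, float] = {}
    remaining = regions
    for tier in CASCADE_TIERS[:-1]:
        claimed = remaining.intersect(tiers[tier])
        out[tier] = 100.0 * claimed.total_bp / total
        remaining = _subtract(remaining, tiers[tier])
    out["other"] = 100.0 * remaining.total_bp / total
    return out


def _subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """a minus b, nucleotide-wise."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    b_arrays = b.arrays()
    for chrom, arr in a.arrays().items():
        cuts = b_arrays.get(chrom)
        if cuts is None or not len(cuts):
            out[chrom] = [tuple(r) for r in arr]
            continue
        kept: List[Tuple[int, int]] = []
        for s, e in arr:
            cur = int(s)
            lo = np.searchsorted(cuts[:, 1], cur, side="right")
            for cs, ce in cuts[lo:]:
                if cs >= e:
                    break
                if cs > cur:
                    kept.append((cur, int(cs)))
                cur = max(cur, int(ce))
                if cur >= e:
                    break
            if cur < e:
                kept.append((cur, int(e)))
        out[chrom] = kept
    return IntervalSet.from_arrays(
        {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in out.items()}
    )


@dataclass
class TEEnrichmentResult:
    subfamily: str
    n_te: int      # DMRs containing >= 1 copy of the subfamily
    n_dmr: int     # DMRs in the group
    big_n_te: int  # genome 500-bp windows overlapped by the subfamily
    big_n_all: int # all genome 500-bp windows
    e_s: float


def subfamily_enrichment(
    dmrs: Sequence[GenomicInterval],
    te_table: Sequence[TECopy],
    genome_grid: Sequence[Bin],
    min_overlap_bp: int = 1,
) -> List[TEEnrichmentResult]:
    """Per-subfamily enrichment E_s of a DMR group over the full bin grid."""
    if not genome_grid:
        raise ValueError("empty genome grid")
    n_all = len(genome_grid)
    n_dmr = len(dmrs)
    out: List[TEEnrichmentResult] = []
    groups: Dict[str, List[GenomicInterval]] = {}
    for t in te_table:
        groups.setdefault(t.subfamily, []).append(t.interval)
    grid_set = IntervalSet.from_bins(b.key for b in genome_grid)
    for sub in sorted(groups):
        ivset = IntervalSet.from_intervals(groups[sub])
        big_n_te = sum(
            1
            for b in genome_grid
            if ivset.overlap_bp_interval(b.chrom, b.start, b.end) >= min_overlap_bp
        )
        if big_n_te == 0:
            logger.info("subfamily %s overlaps no genome window; skipped", sub)
            continue
        n_te = sum(
            1
            for d in dmrs
            if ivset.overlap_bp_interval(d.chrom, d.start, d.end) >= min_overlap_bp
        )
        e_s = (n_te / n_dmr) / (big_n_te / n_all) if n_dmr else float("nan")
        out.append(TEEnrichmentResult(sub, n_te, n_dmr, big_n_te, n_all, e_s))
    return out


def copy_methylation(
    te_copies: Sequence[TECopy],
    cpg_meth_table: Sequence[Tuple[str, int, float, int]],  # (chrom, pos, meth, coverage)
    min_coverage: int = 5,
) -> Dict[str, Optional[float]]:
    """Unweighted mean methylation per TE copy over covered CpGs.

    Only CpGs with coverage >= min_coverage count; copies with no passing
    CpG report None.  Duplicate (chrom, pos) rows are de-duplicated first.
    """
    dedup: Dict[Tuple[str, int], Tuple[float, int]] = {}
    for chrom, pos, meth, cov in cpg_meth_table:
        if not (0.0 <= meth <= 1.0):
            raise ValueError(f"methylation {meth} at {chrom}:{pos} outside [0, 1]")
        dedup[(chrom, pos)] = (meth, cov)

    by_chrom: Dict[str, List[Tuple[int, float]]] = {}
    for (chrom, pos), (meth, cov) in dedup.items():
        if cov >= min_coverage:
            by_chrom.setdefault(chrom, []).append((pos, meth))
    pos_arrays = {
        c: np.array(sorted(v), dtype=np.float64).reshape(-1, 2)
        for c, v in by_chrom.items()
    }

    out: Dict[str, Optional[float]] = {}
    for i, t in enumerate(te_copies):
        arr = pos_arrays.get(t.interval.chrom)
        label = f"{t.subfamily}|{_label(t.interval)}"
        if arr is None or not len(arr):
            out[label] = None
            continue
        lo = np.searchsorted(arr[:, 0], t.interval.start, side="left")
        hi = np.searchsorted(arr[:, 0], t.interval.end, side="left")
        out[label] = float(arr[lo:hi, 1].mean()) if hi > lo else None
    return out
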