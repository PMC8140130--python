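"""Promoter/enhancer definitions, cancer-enhancer DMRs and gene assignment.

Promoters come in two flavours, both strand-oriented around a transcript's
TSS: a 1-kb core (500 bp up- and downstream) used for the tumor-suppressor
promoter tests, and a 2.5-kb window (2 kb upstream, 500 bp downstream) used
wherever merged DMRs must be purged of promoter overlap.  Cancer-enhancer
DMRs (ceDMRs) are merged non-promoter DMRs falling in a region labeled as an
active enhancer state in at least one reference epigenome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .genome_model import (
    ACTIVE_ENHANCER_STATES_18,
    TSS_STATES_18,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    SegmentationStack,
)
from .dmr_compare import OverlapTest, shared_overlap_test

logger = logging.getLogger(__name__)

DEFAULT_MAX_TSS_DISTANCE = 500_000


@dataclass
class PromoterSet:
    kind: str  # "core_1kb" | "extended_2p5kb"
    intervals: List[Tuple[GenomicInterval, str]]  # (window, gene_id)

    def interval_set(self) -> IntervalSet:
        return IntervalSet.from_intervals(iv for iv, _ in self.intervals)

    def genes_overlapping(self, regions: Sequence[GenomicInterval]) -> Set[str]:
        """Gene ids with >= 1 bp overlap between any transcript promoter and
        any region (any-transcript logic collapses to gene level)."""
        region_set = IntervalSet.from_intervals(regions)
        return {
            gid
            for iv, gid in self.intervals
            if region_set.overlaps_interval(iv.chrom, iv.start, iv.end)
        }


PROMOTER_FLANKS = {"core_1kb": (500, 500), "extended_2p5kb": (2000, 500)}


def define_promoters(
    genes: Sequence[GeneModel],
    kind: str,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> PromoterSet:
    """Strand-oriented promoter windows around every transcript's TSS.

    Upstream/downstream flanks follow gene orientation; windows are clipped
    at chromosome bounds when sizes are supplied.
    """
    if kind not in PROMOTER_FLANKS:
        raise ValueError(f"unknown promoter kind {kind!r}")
    up, down = PROMOTER_FLANKS[kind]
    out: List[Tuple[GenomicInterval, str]] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - up, g.tss + down
        else:
            start, end = g.tss - down, g.tss + up
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        if start < end:
            out.append((GenomicInterval(g.chrom, start, end), g.gene_id))
    return PromoterSet(kind=kind, intervals=out)


def active_enhancer_union(stack: SegmentationStack) -> IntervalSet:
    """Regions labeled 9_EnhA1 or 10_EnhA2 in >= 1 epigenome (18-state model)."""
    if stack.model != "18-state":
        raise ValueError("active-enhancer union is defined on the 18-state model")
    return stack.state_union(ACTIVE_ENHANCER_STATES_18)


def merge_consecutive(dmr_bins: Sequence[Tuple[str, int]]) -> List[GenomicInterval]:
    """Merge maximal runs of grid-adjacent 500-bp bins into single intervals.

    Call once per (direction, group): merging is pure coordinate adjacency
    and must never join bins of opposite direction.
    """
    return IntervalSet.from_bins(dmr_bins).intervals()


@dataclass
class CeDMRSet:
    """Merged non-promoter DMRs overlapping the active-enhancer union."""

    direction: str
    dmrs: List[GenomicInterval]
    n_input: int
    n_promoter_discarded: int


def classify_ce_dmrs(
    merged: Sequence[GenomicInterval],
    promoters_extended: PromoterSet,
    enhancer_union: IntervalSet,
    direction: str = "",
) -> CeDMRSet:
    """Discard merged DMRs touching any 2.5-kb promoter, then require >= 1 bp
    overlap with the active-enhancer union (order fixed: discard first)."""
    prom = promoters_extended.interval_set()
    non_promoter = [
        d for d in merged if not prom.overlaps_interval(d.chrom, d.start, d.end)
    ]
    kept = [
        d
        for d in non_promoter
        if enhancer_union.overlaps_interval(d.chrom, d.start, d.end)
    ]
    logger.info(
        "ceDMR classification (%s): %d input, %d promoter-discarded, %d retained",
        direction or "?", len(merged), len(merged) - len(non_promoter), len(kept),
    )
    return CeDMRSet(
        direction=direction,
        dmrs=kept,
        n_input=len(merged),
        n_promoter_discarded=len(merged) - len(non_promoter),
    )


def regulatory_breakdown(
    dmrs: Sequence[GenomicInterval],
    promoters: IntervalSet,
    enhancer_union: IntervalSet,
) -> Dict[str, float]:
    """Mutually exclusive four-way partition of DMRs by regulatory annotation.

    The promoter set here is the union of gene-model 2.5-kb windows and the
    TSS-like chromatin states (1-4) present in >= 1 epigenome.  Percentages
    sum to 100 for nonempty input.
    """
    counts = {"both": 0, "promoter_only": 0, "enhancer_only": 0, "neither": 0}
    for d in dmrs:
        in_p = promoters.overlaps_interval(d.chrom, d.start, d.end)
        in_e = enhancer_union.overlaps_interval(d.chrom, d.start, d.end)
        if in_p and in_e:
            counts["both"] += 1
        elif in_p:
            counts["promoter_only"] += 1
        elif in_e:
            counts["enhancer_only"] += 1
        else:
            counts["neither"] += 1
    n = len(dmrs)
    return {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}


def promoter_like_union(
    genes: Sequence[GeneModel],
    stack: SegmentationStack,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> IntervalSet:
    """RefGene-style 2.5-kb promoter windows unioned with TSS states 1-4
    (>= 1 epigenome), the promoter definition of the regulatory breakdown."""
    refgene = define_promoters(genes, "extended_2p5kb", chrom_sizes).interval_set()
    states = stack.state_union(TSS_STATES_18)
    return refgene.union(states)


@dataclass
class GeneAssignment:
    """region label -> (gene_id, signed edge distance to the nearest TSS)."""

    assignments: Dict[str, Tuple[str, int]]
    unassigned: List[str]
    max_distance: int


def _edge_distance(region: GenomicInterval, tss: int) -> int:
    """Signed distance from the region's nearest edge to the TSS; 0 if the
    TSS lies inside [start, end). Positive = TSS right of the region."""
    if region.start <= tss < region.end:
        return 0
    if tss >= region.end:
        return tss - (region.end - 1)
    return tss - region.start  # negative


def assign_to_gene(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_TSS_DISTANCE,
) -> GeneAssignment:
    """Assign each region to the gene with the nearest TSS (edge distance).

    Ties on |distance| break lexicographically by gene_id with a warning;
    regions whose nearest TSS is farther than ``max_distance`` stay
    unassigned.
    """
    if not genes:
        raise ValueError("empty gene list")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    assignments: Dict[str, Tuple[str, int]] = {}
    unassigned: List[str] = []
    n_ties = 0
    for region in regions:
        label = f"{region.chrom}:{region.start}-{region.end}"
        best: Optional[Tuple[int, str, int]] = None  # (|d|, gene_id, signed d)
        for g in by_chrom.get(region.chrom, ()):
            d = _edge_distance(region, g.tss)
            cand = (abs(d), g.gene_id, d)
            if best is None or cand < best:
                if best is not None and cand[0] == best[0] and cand[1] != best[1]:
                    n_ties += 1
                best = cand
        if best is None or best[0] > max_distance:
            unassigned.append(label)
        else:
            assignments[label] = (best[1], best[2])
    if n_ties:
        logger.warning("nearest-TSS assignment: %d ties broken by gene id", n_ties)
    return GeneAssignment(assignments, unassigned, max_distance)


@dataclass
class GeneSetOverlapTest:
    universe_size: int
    set_sizes: Dict[str, int]
    observed: int
    test: OverlapTest


def geneset_regulatory_overlap(
    gene_sets: Mapping[str, Set[str]], universe: Sequence[str]
) -> GeneSetOverlapTest:
    """Upper-tail hypergeometric test on the intersection of two gene sets
    against a fixed gene universe (same log-space kernel as the bin tests)."""
    uni = set(universe)
    if len(gene_sets) != 2:
        raise ValueError("exactly two gene sets required")
    for name, s in gene_sets.items():
        stray = s - uni
        if stray:
            raise ValueError(f"set {name!r} has genes outside the universe: {sorted(stray)[:10]}")
    (name_a, set_a), (name_b, set_b) = sorted(gene_sets.items())
    observed = len(set_a & set_b)
    test = shared_overlap_test(len(set_a), len(set_b), len(uni), observed)
    return GeneSetOverlapTest(
        universe_size=len(uni),
        set_sizes={name_a: len(set_a), name_b: len(set_b)},
        observed=observed,
        test=test,
    )


def pathway_regulatory_table(
    pathway_genes: Sequence[str],
    dmrs: Sequence[GenomicInterval],
    promoters_extended: PromoterSet,
    enhancers_unmerged: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_TSS_DISTANCE,
) -> Dict[str, Dict[str, bool]]:
    """Per pathway gene: does a DMR hit its 2.5-kb promoter, and/or an
    enhancer assigned to it?

    Enhancer hits use unmerged enhancer regions purged of promoter overlap
    before nearest-gene assignment; an enhancer counts iff it both contains a
    DMR and is assigned to the gene.
    """
    known = {g.gene_id for g in genes}
    resolvable = [g for g in pathway_genes if g in known]
    missing = sorted(set(pathway_genes) - known)
    if missing:
        logger.warning("pathway genes without gene models (excluded): %s", missing[:10])

    promoter_hits = promoters_extended.genes_overlapping(dmrs)

    prom = promoters_extended.interval_set()
    clean_enh = [
        e for e in enhancers_unmerged if not prom.overlaps_interval(e.chrom, e.start, e.end)
    ]
    assignment = assign_to_gene(clean_enh, genes, max_distance)
    dmr_set = IntervalSet.from_intervals(dmrs)
    enhancer_hits: Set[str] = set()
    for e in clean_enh:
        label = f"{e.chrom}:{e.start}-{e.end}"
        if label in assignment.assignments and dmr_set.overlaps_interval(
            e.chrom, e.start, e.end
        ):
            enhancer_hits.add(assignment.assignments[label][0])

    return {
        g: {"promoter_hit": g in promoter_hits, "enhancer_hit": g in enhancer_hits}
        for g in resolvable
    }
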