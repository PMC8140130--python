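"""Seeded synthetic-genome generator for offline, end-to-end testing.

The generator emulates the statistical structure the pipeline assumes, at a
toy scale: clustered CpGs at islands seeded near TSSs, chromatin-state
segmentations with realistic dwell lengths whose TSS/enhancer states are
correlated across epigenomes, TE subfamilies with one designated
hypomethylated subfamily, promoter/island-biased array probes, DMRs planted
with configurable enrichment over annotation categories and a configurable
shared fraction between two pseudo-cancers, lognormal expression with
planted fold changes, beta matrices with planted shifts, and toy consensus
motifs embedded in short synthetic DMR sequences.

Every generator is a pure function of its config and seed: one global seed
fans out into fixed per-component child streams, so regenerating one layer
never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome_model import (
    ACTIVE_ENHANCER_STATES_18,
    BIN_SIZE,
    ROADMAP_15_STATES,
    ROADMAP_18_STATES,
    BackgroundSet,
    Bin,
    BinKey,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    IntervalSet,
    ProbeSet,
    SegmentationStack,
    SignalPresence,
    TECopy,
    build_background,
    build_bin_grid,
)
from .dmr_compare import SampleDMRCall

# fixed child-stream indices of the global seed fan-out
_STREAMS = {
    "genome": 0,
    "dmrs": 1,
    "expression": 2,
    "betas": 3,
    "motifs": 4,
    "te_methylation": 5,
    "presence": 6,
}


def child_rng(seed: int, component: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[component]])


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic cohort (defaults are the conditions
    every test and the acceptance run use)."""

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}
    )
    n_genes: int = 360
    island_fraction_of_tss: float = 0.7
    n_random_islands: int = 150
    island_length: int = 1_000
    cpg_rate_in_islands: float = 0.08   # CpGs per bp inside islands
    cpg_rate_outside: float = 0.004
    n_epigenomes_18: int = 6
    n_epigenomes_15: int = 4
    mean_dwell: int = 2_000             # bp, neutral chromatin states
    quies_dwell: int = 10_000
    n_enhancer_loci: int = 400
    enhancer_length: int = 700
    enhancer_epigenome_rate: float = 0.5
    tss_epigenome_rate: float = 0.8
    # TE subfamilies: (name, copy count, copy length)
    te_subfamilies: List[Tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("SYNL1", 400, 350),
            ("SYNL2", 400, 350),
            ("SYNS1", 350, 250),
            ("MERX", 300, 400),
        ]
    )
    hypomethylated_subfamily: str = "MERX"
    n_probes: int = 4_000
    probe_promoter_bias: float = 0.7    # fraction of probes drawn near islands/TSSs
    blacklist_fraction: float = 0.005
    signal_rate: float = 0.85           # per-sample fraction of bins with signal
    # DMR planting
    n_hyper: Dict[str, int] = field(default_factory=lambda: {"A": 1400, "B": 900})
    n_hypo: Dict[str, int] = field(default_factory=lambda: {"A": 700, "B": 450})
    n_samples: Dict[str, int] = field(default_factory=lambda: {"A": 3, "B": 5})
    min_support: Dict[str, int] = field(default_factory=lambda: {"A": 2, "B": 2})
    shared_fraction: float = 0.15
    dropout: float = 0.1
    n_noise_calls: int = 30             # per-sample singleton noise calls
    hyper_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.45, "enhancer": 0.30, "te": 0.05, "intergenic": 0.20
        }
    )
    hypo_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.08, "enhancer": 0.12, "te": 0.35, "intergenic": 0.45
        }
    )
    # expression
    n_tumor: int = 30
    n_normal: int = 29
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 1.2
    expr_noise_sd: float = 0.4          # per-sample log2 noise
    # betas
    beta_island: float = 0.15
    beta_background: float = 0.80
    beta_noise_sd: float = 0.05
    beta_shift: float = 0.25
    n_beta_tumor: int = 20
    n_beta_normal: int = 20
    # motifs
    n_tfs: int = 8
    motif_length: int = 8
    motif_target_rate: float = 0.6
    motif_background_rate: float = 0.1
    dmr_sequence_length: int = 200
    # TE methylation
    te_cpg_spacing: int = 40
    te_meth_normal: float = 0.80
    te_meth_tumor_target: float = 0.35
    te_coverage_mean: float = 10.0
    n_te_samples: int = 4               # per group

    def validate(self) -> None:
        for w in (self.hyper_weights, self.hypo_weights):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("category mixture weights must sum to 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    annotation: GenomeAnnotation
    stack18: SegmentationStack
    stack15: SegmentationStack
    enhancer_loci: List[GenomicInterval]
    presence: SignalPresence
    background: BackgroundSet
    grid: List[Bin]


def _sample_positions(rng: np.random.Generator, length: int, rate: float) -> np.ndarray:
    n = rng.poisson(rate * length)
    return np.unique(rng.integers(0, length, size=n))


def generate_genome(config: FixtureConfig) -> SyntheticGenome:
    config.validate()
    rng = child_rng(config.seed, "genome")
    sizes = dict(config.chrom_sizes)
    chroms = sorted(sizes)
    genome_bp = sum(sizes.values())
    if config.n_genes * 25_000 > genome_bp:
        raise ValueError("gene count infeasible for genome size")

    # --- genes -------------------------------------------------------------
    genes: List[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(2_000, 20_000))
        start = int(rng.integers(5_000, sizes[chrom] - length - 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"GENE{i:04d}",
                chrom=chrom,
                strand=strand,
                body=GenomicInterval(chrom, start, start + length),
            )
        )

    # --- CpG islands: near a fraction of TSSs, plus random ones -------------
    island_ivs: List[GenomicInterval] = []
    half = config.island_length // 2
    for g in genes:
        if rng.random() < config.island_fraction_of_tss:
            s = max(0, g.tss - half)
            island_ivs.append(GenomicInterval(g.chrom, s, min(s + config.island_length, sizes[g.chrom])))
    for _ in range(config.n_random_islands):
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, sizes[chrom] - config.island_length))
        island_ivs.append(GenomicInterval(chrom, s, s + config.island_length))
    islands = IntervalSet.from_intervals(island_ivs)

    # --- CpG positions: denser inside islands -------------------------------
    cpg_positions: Dict[str, np.ndarray] = {}
    island_arrays = islands.arrays()
    for chrom in chroms:
        base = _sample_positions(rng, sizes[chrom], config.cpg_rate_outside)
        extra: List[np.ndarray] = []
        for s, e in island_arrays.get(chrom, np.empty((0, 2), dtype=np.int64)):
            pos = s + _sample_positions(rng, int(e - s), config.cpg_rate_in_islands)
            extra.append(pos)
        allpos = np.unique(np.concatenate([base] + extra)) if extra else base
        cpg_positions[chrom] = allpos.astype(np.int64)

    # --- enhancer loci, shared across epigenomes ----------------------------
    enhancer_loci: List[GenomicInterval] = []
    for _ in range(config.n_enhancer_loci):
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, sizes[chrom] - config.enhancer_length))
        enhancer_loci.append(GenomicInterval(chrom, s, s + config.enhancer_length))

    # --- segmentations ------------------------------------------------------
    stack18 = _generate_stack(rng, config, sizes, genes, enhancer_loci, model="18-state")
    stack15 = _generate_stack(rng, config, sizes, genes, enhancer_loci, model="15-state")

    # --- TEs ----------------------------------------------------------------
    te_table: List[TECopy] = []
    for name, count, length in config.te_subfamilies:
        family = f"{name}-fam"
        for _ in range(count):
            chrom = chroms[rng.integers(0, len(chroms))]
            s = int(rng.integers(0, sizes[chrom] - length))
            te_table.append(
                TECopy(GenomicInterval(chrom, s, s + length), name, family, "Synthetic/TE")
            )

    # --- probes: promoter/island biased -------------------------------------
    positions: Dict[str, List[int]] = {c: [] for c in chroms}
    island_list = islands.intervals()
    for _ in range(config.n_probes):
        if island_list and rng.random() < config.probe_promoter_bias:
            iv = island_list[rng.integers(0, len(island_list))]
            pos = int(rng.integers(iv.start, iv.end))
            positions[iv.chrom].append(pos)
        else:
            chrom = chroms[rng.integers(0, len(chroms))]
            positions[chrom].append(int(rng.integers(0, sizes[chrom])))
    pid = 0
    probe_pos: Dict[str, np.ndarray] = {}
    probe_ids: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        uniq = sorted(set(positions[chrom]))
        probe_pos[chrom] = np.array(uniq, dtype=np.int64)
        probe_ids[chrom] = np.array([f"cg{pid + i:06d}" for i in range(len(uniq))], dtype=object)
        pid += len(uniq)
    probes = ProbeSet(platform="synthetic", positions=probe_pos, probe_ids=probe_ids)

    # --- grid, blacklist, per-sample signal presence ------------------------
    grid = build_bin_grid(sizes)
    keys = [b.key for b in grid]
    n_black = int(config.blacklist_fraction * len(grid))
    black_idx = rng.choice(len(grid), size=n_black, replace=False)
    blacklist = {keys[i] for i in black_idx}

    prng = child_rng(config.seed, "presence")
    samples: Dict[str, Set[BinKey]] = {}
    total_samples = config.n_samples["A"] + config.n_samples["B"]
    for s in range(total_samples):
        mask = prng.random(len(grid)) < config.signal_rate
        samples[f"S{s:02d}"] = {k for k, m in zip(keys, mask) if m}
    presence = SignalPresence(samples=samples)

    annotation = GenomeAnnotation(
        chrom_sizes=sizes,
        genes=genes,
        cpg_islands=islands,
        cpg_positions=cpg_positions,
        blacklist_bins=blacklist,
        enhancer_catalogs={"synthetic_enhancers": IntervalSet.from_intervals(enhancer_loci)},
        te_table=te_table,
        probe_manifests={"synthetic": probes},
    )
    annotation.validate()

    background = build_background(grid, cpg_positions, blacklist, presence)
    return SyntheticGenome(
        annotation=annotation,
        stack18=stack18,
        stack15=stack15,
        enhancer_loci=enhancer_loci,
        presence=presence,
        background=background,
        grid=grid,
    )


def _generate_stack(
    rng: np.random.Generator,
    config: FixtureConfig,
    sizes: Mapping[str, int],
    genes: Sequence[GeneModel],
    enhancer_loci: Sequence[GenomicInterval],
    model: str,
) -> SegmentationStack:
    """Tile each chromosome per epigenome: forced TSS/enhancer segments shared
    across epigenomes (with per-epigenome inclusion), gaps filled by a dwell
    chain over neutral states."""
    if model == "18-state":
        n_epi = config.n_epigenomes_18
        tss_state, flank_state = "1_TssA", "2_TssFlnk"
        enh_states = list(ACTIVE_ENHANCER_STATES_18)
        # TSS-proximal states only ever appear at TSSs, never in random fill
        forced_states = {tss_state, flank_state, *enh_states,
                         "3_TssFlnkU", "4_TssFlnkD"}
        neutral = [s for s in ROADMAP_18_STATES if s not in forced_states]
        quies = "18_Quies"
    else:
        n_epi = config.n_epigenomes_15
        tss_state, flank_state = "1_TssA", "2_TssAFlnk"
        enh_states = ["7_Enh"]
        forced_states = {tss_state, flank_state, *enh_states}
        neutral = [s for s in ROADMAP_15_STATES if s not in forced_states]
        quies = "15_Quies"

    epigenomes: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    for e in range(n_epi):
        eid = f"E{e:02d}" if model == "18-state" else f"F{e:02d}"
        segs: List[Tuple[GenomicInterval, str]] = []
        for chrom in sorted(sizes):
            forced: List[Tuple[int, int, str]] = []
            for g in genes:
                if g.chrom != chrom or rng.random() >= config.tss_epigenome_rate:
                    continue
                s = max(0, g.tss - 500)
                forced.append((s, min(g.tss + 500, sizes[chrom]), tss_state))
                if model == "18-state":
                    up = "3_TssFlnkU" if rng.random() < 0.5 else flank_state
                    down = "4_TssFlnkD" if rng.random() < 0.5 else flank_state
                else:
                    up = down = flank_state
                if g.tss - 900 >= 0:
                    forced.append((g.tss - 900, g.tss - 500, up))
                if g.tss + 500 + 400 <= sizes[chrom]:
                    forced.append((g.tss + 500, g.tss + 900, down))
            for iv in enhancer_loci:
                if iv.chrom != chrom or rng.random() >= config.enhancer_epigenome_rate:
                    continue
                state = enh_states[rng.integers(0, len(enh_states))]
                forced.append((iv.start, iv.end, state))
            forced.sort()
            # drop forced segments overlapping an earlier one
            clean: List[Tuple[int, int, str]] = []
            last_end = 0
            for s, e2, st in forced:
                if s >= last_end:
                    clean.append((s, e2, st))
                    last_end = e2
            # fill gaps with a dwell chain
            cursor = 0
            for s, e2, st in clean + [(sizes[chrom], sizes[chrom], "")]:
                while cursor < s:
                    state = neutral[rng.integers(0, len(neutral))]
                    dwell = config.quies_dwell if state == quies else config.mean_dwell
                    length = max(200, int(rng.exponential(dwell)))
                    end = min(cursor + length, s)
                    segs.append((GenomicInterval(chrom, cursor, end), state))
                    cursor = end
                if st:
                    segs.append((GenomicInterval(chrom, s, e2), st))
                    cursor = e2
        epigenomes[eid] = segs
    return SegmentationStack(model=model, epigenomes=epigenomes)


# ---------------------------------------------------------------------------
# DMR planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedDMRs:
    consensus: Dict[str, Dict[str, Set[BinKey]]]   # cancer -> direction -> bins
    calls: Dict[str, List[SampleDMRCall]]          # cancer -> per-sample calls
    category_pools: Dict[str, List[BinKey]]
    truth: Dict[str, Dict[str, List[BinKey]]]      # cancer -> category -> planted bins


def build_category_pools(
    genome: SyntheticGenome, config: FixtureConfig
) -> Dict[str, List[BinKey]]:
    """Disjoint pools of background bins by annotation category.

    Priority order te > promoter > enhancer > intergenic so the TE pool stays
    targetable for hypoDMR planting.
    """
    from .regulatory import define_promoters

    target = config.hypomethylated_subfamily
    te_set = IntervalSet.from_intervals(
        t.interval for t in genome.annotation.te_table if t.subfamily == target
    )
    promoters = define_promoters(
        genome.annotation.genes, "extended_2p5kb", genome.annotation.chrom_sizes
    ).interval_set()
    enhancers = genome.stack18.state_union(ACTIVE_ENHANCER_STATES_18)

    pools: Dict[str, List[BinKey]] = {"te": [], "promoter": [], "enhancer": [], "intergenic": []}
    for chrom, start in genome.background.bins:
        end = start + BIN_SIZE
        if te_set.overlaps_interval(chrom, start, end):
            pools["te"].append((chrom, start))
        elif promoters.overlaps_interval(chrom, start, end):
            pools["promoter"].append((chrom, start))
        elif enhancers.overlaps_interval(chrom, start, end):
            pools["enhancer"].append((chrom, start))
        else:
            pools["intergenic"].append((chrom, start))
    return pools


def _draw_category_bins(
    rng: np.random.Generator,
    pools: Mapping[str, Sequence[BinKey]],
    weights: Mapping[str, float],
    n: int,
    used: Set[BinKey],
) -> Dict[str, List[BinKey]]:
    counts = rng.multinomial(n, [weights[c] for c in ("promoter", "enhancer", "te", "intergenic")])
    out: Dict[str, List[BinKey]] = {}
    for cat, k in zip(("promoter", "enhancer", "te", "intergenic"), counts):
        avail = [b for b in pools[cat] if b not in used]
        if k > len(avail):
            raise ValueError(
                f"cannot plant {k} DMRs in category {cat!r}: only {len(avail)} bins available"
            )
        idx = rng.choice(len(avail), size=k, replace=False)
        chosen = [avail[i] for i in idx]
        used.update(chosen)
        out[cat] = chosen
    return out


def plant_dmrs(
    config: FixtureConfig,
    genome: SyntheticGenome,
    uniform: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> PlantedDMRs:
    """Plant two pseudo-cancers' DMR consensus sets and per-sample calls.

    Cancer B copies a fraction ``shared_fraction`` of cancer A's bins per
    direction; the rest are drawn fresh.  With ``uniform=True`` the category
    mixture is ignored and bins are drawn uniformly from the background (the
    null condition of the overlap-test calibration).
    """
    rng = rng if rng is not None else child_rng(config.seed, "dmrs")
    pools = {} if uniform else build_category_pools(genome, config)
    bg_bins = list(genome.background.bins)

    consensus: Dict[str, Dict[str, Set[BinKey]]] = {}
    truth: Dict[str, Dict[str, List[BinKey]]] = {}
    for cancer in ("A", "B"):
        consensus[cancer] = {"hyper": set(), "hypo": set()}
        truth[cancer] = {}
        used: Set[BinKey] = set()
        for direction, n_req, weights in (
            ("hyper", config.n_hyper[cancer], config.hyper_weights),
            ("hypo", config.n_hypo[cancer], config.hypo_weights),
        ):
            n_fresh = n_req
            if cancer == "B" and config.shared_fraction > 0:
                donors = sorted(consensus["A"][direction])
                n_copy = min(int(round(config.shared_fraction * n_req)), len(donors))
                idx = rng.choice(len(donors), size=n_copy, replace=False)
                copied = [donors[i] for i in idx if donors[i] not in used]
                consensus[cancer][direction].update(copied)
                used.update(copied)
                n_fresh = n_req - len(copied)
            if uniform:
                avail = [b for b in bg_bins if b not in used]
                idx = rng.choice(len(avail), size=n_fresh, replace=False)
                fresh = [avail[i] for i in idx]
                used.update(fresh)
                truth[cancer][direction] = fresh
            else:
                by_cat = _draw_category_bins(rng, pools, weights, n_fresh, used)
                fresh = [b for bins in by_cat.values() for b in bins]
                truth[cancer][direction] = fresh
            consensus[cancer][direction].update(fresh)

    calls: Dict[str, List[SampleDMRCall]] = {}
    offset = 0
    for cancer in ("A", "B"):
        n_s = config.n_samples[cancer]
        sample_ids = [f"S{offset + i:02d}" for i in range(n_s)]
        offset += n_s
        cancer_calls: List[SampleDMRCall] = []
        called: Dict[str, Set[BinKey]] = {sid: set() for sid in sample_ids}
        for direction, bins in consensus[cancer].items():
            for b in sorted(bins):
                for sid in sample_ids:
                    if rng.random() >= config.dropout:
                        cancer_calls.append(SampleDMRCall(sid, b, direction))
                        called[sid].add(b)
        # singleton noise calls that must not survive recurrence
        planted_all = consensus[cancer]["hyper"] | consensus[cancer]["hypo"]
        for sid in sample_ids:
            for _ in range(config.n_noise_calls):
                b = bg_bins[rng.integers(0, len(bg_bins))]
                if b in planted_all or b in called[sid]:
                    continue
                direction = "hyper" if rng.random() < 0.5 else "hypo"
                cancer_calls.append(SampleDMRCall(sid, b, direction))
                called[sid].add(b)
        calls[cancer] = cancer_calls

    return PlantedDMRs(consensus=consensus, calls=calls, category_pools=pools, truth=truth)


# ---------------------------------------------------------------------------
# expression / betas / motifs / TE methylation
# ---------------------------------------------------------------------------

def plant_expression(
    config: FixtureConfig,
    gene_ids: Sequence[str],
    planted_fold_changes: Mapping[str, float],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Gene x sample RPKM matrix with lognormal baselines and planted tumor
    log2 fold changes; returns (matrix, sample -> group labels)."""
    rng = rng if rng is not None else child_rng(config.seed, "expression")
    dangling = set(planted_fold_changes) - set(gene_ids)
    if dangling:
        raise ValueError(f"planted fold changes for unknown genes: {sorted(dangling)[:5]}")
    samples = [f"T{i:02d}" for i in range(config.n_tumor)] + [
        f"N{i:02d}" for i in range(config.n_normal)
    ]
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    base_log2 = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=len(gene_ids))
    data = np.empty((len(gene_ids), len(samples)))
    for i, g in enumerate(gene_ids):
        fc = planted_fold_changes.get(g, 0.0)
        mu_t = base_log2[i] + fc
        mu_n = base_log2[i]
        vals_t = rng.normal(mu_t, config.expr_noise_sd, size=config.n_tumor)
        vals_n = rng.normal(mu_n, config.expr_noise_sd, size=config.n_normal)
        data[i] = np.concatenate([2.0 ** vals_t, 2.0 ** vals_n])
    return pd.DataFrame(data, index=list(gene_ids), columns=samples), groups


def plant_betas(
    config: FixtureConfig,
    genome: SyntheticGenome,
    hyper_bins: Set[BinKey],
    hypo_bins: Set[BinKey],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, Dict[str, str], Dict[str, str]]:
    """Probe x sample beta matrix with planted tumor shifts inside DMRs.

    Baselines are low inside islands and high outside; probes in planted
    hyper bins gain ``beta_shift`` in tumor samples, probes in hypo bins lose
    it.  Returns (betas, sample -> group, sample -> patient)."""
    rng = rng if rng is not None else child_rng(config.seed, "betas")
    probes = genome.annotation.probe_manifests["synthetic"]
    islands = genome.annotation.cpg_islands
    hyper_set = IntervalSet.from_bins(hyper_bins) if hyper_bins else None
    hypo_set = IntervalSet.from_bins(hypo_bins) if hypo_bins else None

    samples = [f"BT{i:02d}" for i in range(config.n_beta_tumor)] + [
        f"BN{i:02d}" for i in range(config.n_beta_normal)
    ]
    groups = {s: ("tumor" if s.startswith("BT") else "normal") for s in samples}
    patients = {s: f"P-{s}" for s in samples}

    rows = []
    index = []
    for chrom in sorted(probes.positions):
        for pid, pos in zip(probes.probe_ids[chrom], probes.positions[chrom]):
            pos = int(pos)
            in_island = islands is not None and islands.overlaps_interval(chrom, pos, pos + 1)
            base = config.beta_island if in_island else config.beta_background
            shift = 0.0
            if hyper_set is not None and hyper_set.overlaps_interval(chrom, pos, pos + 1):
                # hypermethylation starts from a lowly methylated baseline
                base, shift = config.beta_island, config.beta_shift
            elif hypo_set is not None and hypo_set.overlaps_interval(chrom, pos, pos + 1):
                # hypomethylation starts from a highly methylated baseline
                base, shift = config.beta_background, -config.beta_shift
            noise = rng.normal(0.0, config.beta_noise_sd, size=len(samples))
            vals = np.clip(
                base
                + noise
                + np.where([groups[s] == "tumor" for s in samples], shift, 0.0),
                0.0,
                1.0,
            )
            rows.append(vals)
            index.append(str(pid))
    return pd.DataFrame(rows, index=index, columns=samples), groups, patients


_ALPHABET = np.array(list("ACGT"))


def plant_motifs(
    config: FixtureConfig,
    dmr_labels: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, List[str]]]:
    """Toy motif layer: per synthetic TF a random consensus, embedded into
    short synthetic DMR sequences at the target rate for 'enriched' TFs and
    at the background rate otherwise; presence by exact consensus scan.

    Returns (motif enrichment table, DMR x TF binary hit matrix, TF -> motif
    mapping).  The enrichment table carries columns motif, tf, q, fraction.
    """
    from scipy.stats import binomtest
    from statsmodels.stats.multitest import multipletests

    rng = rng if rng is not None else child_rng(config.seed, "motifs")
    tfs = [f"TF{i:02d}" for i in range(config.n_tfs)]
    motifs = {
        tf: "".join(rng.choice(_ALPHABET, size=config.motif_length)) for tf in tfs
    }
    enriched = set(tfs[: config.n_tfs // 2])  # first half planted as enriched

    seqs: Dict[str, str] = {}
    for label in dmr_labels:
        seq = list(rng.choice(_ALPHABET, size=config.dmr_sequence_length))
        for tf in tfs:
            rate = config.motif_target_rate if tf in enriched else config.motif_background_rate
            if rng.random() < rate:
                pos = int(rng.integers(0, config.dmr_sequence_length - config.motif_length))
                seq[pos: pos + config.motif_length] = list(motifs[tf])
        seqs[label] = "".join(seq)

    hits = pd.DataFrame(
        {tf: [1 if motifs[tf] in seqs[d] else 0 for d in dmr_labels] for tf in tfs},
        index=list(dmr_labels),
    )
    # expected chance rate of an exact L-mer hit in a sequence of this length
    p0 = 1.0 - (1.0 - 0.25 ** config.motif_length) ** (
        config.dmr_sequence_length - config.motif_length + 1
    )
    p_raw = []
    for tf in tfs:
        k = int(hits[tf].sum())
        p_raw.append(binomtest(k, len(dmr_labels), p0, alternative="greater").pvalue)
    q = multipletests(p_raw, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "motif": [f"{motifs[tf]}-motif" for tf in tfs],
            "tf": tfs,
            "q": q,
            "fraction": [hits[tf].mean() for tf in tfs],
        }
    )
    tf_to_motifs = {tf: [f"{motifs[tf]}-motif"] for tf in tfs}
    return table, hits, tf_to_motifs


def plant_te_methylation(
    config: FixtureConfig,
    te_table: Sequence[TECopy],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, List[Tuple[str, int, float, int]]], Dict[str, str]]:
    """Per-pseudo-sample CpG methylation tables over TE copies.

    The designated subfamily's copies lose methylation in tumor samples;
    coverage is Poisson so the >= 5x filter is exercised.  Returns
    (sample -> rows of (chrom, pos, meth, coverage), sample -> group)."""
    rng = rng if rng is not None else child_rng(config.seed, "te_methylation")
    samples = [f"MT{i:02d}" for i in range(config.n_te_samples)] + [
        f"MN{i:02d}" for i in range(config.n_te_samples)
    ]
    groups = {s: ("tumor" if s.startswith("MT") else "normal") for s in samples}
    tables: Dict[str, List[Tuple[str, int, float, int]]] = {s: [] for s in samples}
    for t in te_table:
        cpgs = list(range(t.interval.start + 5, t.interval.end - 5, config.te_cpg_spacing))
        for s in samples:
            tumor = groups[s] == "tumor"
            level = (
                config.te_meth_tumor_target
                if tumor and t.subfamily == config.hypomethylated_subfamily
                else config.te_meth_normal
            )
            for pos in cpgs:
                meth = float(np.clip(rng.normal(level, 0.08), 0.0, 1.0))
                cov = int(rng.poisson(config.te_coverage_mean))
                tables[s].append((t.interval.chrom, pos, meth, cov))
    return tables, groups
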