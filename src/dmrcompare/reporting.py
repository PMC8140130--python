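"""End-to-end orchestration of the comparative analysis on one config.

``run_pipeline`` executes every stage in order — background universe,
recurrent DMRs, category partition and overlap tests, genomic/chromatin
enrichment, ceDMR classification and gene assignment, gene-set tests,
expression integration, motif clustering, TE analyses, array coverage — and
writes each stage's tables before the next begins.  Re-running with the same
config reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import array_coverage as ac
from . import dmr_compare as dc
from . import enrichment as en
from . import expression_motifs as em
from . import regulatory as rg
from . import te_methylation as te
from .fixtures import FixtureConfig, PlantedDMRs, SyntheticGenome
from .fixtures import (
    generate_genome,
    plant_betas,
    plant_dmrs,
    plant_expression,
    plant_motifs,
    plant_te_methylation,
)
from .genome_model import BinKey, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    seed: int
    out_dir: str
    stage_outputs: Dict[str, List[str]] = field(default_factory=dict)
    summary: Dict[str, object] = field(default_factory=dict)

    def record(self, stage: str, *paths: Path) -> None:
        self.stage_outputs.setdefault(stage, []).extend(str(p) for p in paths)


def _bins_to_intervals(bins: Set[BinKey]) -> List[GenomicInterval]:
    return [GenomicInterval(c, s, s + 500) for c, s in sorted(bins)]


def run_pipeline(config: FixtureConfig, out_dir: str | Path) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, out_dir=str(out))

    # ---- stage 1: genome + background --------------------------------------
    genome = generate_genome(config)
    bg = genome.background
    pd.DataFrame(bg.bins, columns=["chrom", "start"]).to_csv(
        out / "background_bins.tsv", sep="\t", index=False
    )
    manifest.record("background", out / "background_bins.tsv")
    manifest.summary["n_background_bins"] = bg.n_bins

    # ---- stage 2: recurrent DMRs, categories, overlap tests ----------------
    planted = plant_dmrs(config, genome)
    recurrent = {
        cancer: dc.call_recurrent(
            planted.calls[cancer],
            n_samples=config.n_samples[cancer],
            min_support=config.min_support[cancer],
            cancer_id=cancer,
        )
        for cancer in ("A", "B")
    }
    cats = dc.categorize(recurrent["A"], recurrent["B"])
    ratios = {c: dc.ratio_of_set(recurrent[c]) for c in ("A", "B")}
    tests = {}
    for direction in ("hyper", "hypo"):
        tests[direction] = dc.overlap_test_from_sets(
            recurrent["A"].bins(direction), recurrent["B"].bins(direction), bg.n_bins
        )
    cat_rows = [{"category": k, "n_bins": v} for k, v in cats.sizes().items()]
    pd.DataFrame(cat_rows).to_csv(out / "dmr_categories.tsv", sep="\t", index=False)
    with open(out / "overlap_tests.json", "w") as fh:
        json.dump({d: asdict(t) for d, t in tests.items()}, fh, indent=2)
    manifest.record("dmr_compare", out / "dmr_categories.tsv", out / "overlap_tests.json")
    manifest.summary.update(
        {
            "category_sizes": cats.sizes(),
            "hyper_hypo_ratio": ratios,
            "overlap_log10_p": {d: tests[d].log10_p for d in tests},
            "n_dmrs": {c: recurrent[c].n_total for c in recurrent},
        }
    )

    # ---- stage 3: genomic + chromatin-state enrichment ---------------------
    ann = genome.annotation
    promoters_ext = rg.define_promoters(ann.genes, "extended_2p5kb", ann.chrom_sizes)
    features = {
        "promoter_2p5kb": promoters_ext.interval_set(),
        "cpg_island": ann.cpg_islands,
        "gene_body": IntervalSet.from_intervals(g.body for g in ann.genes),
        "te": IntervalSet.from_intervals(t.interval for t in ann.te_table),
        "enhancer_catalog": ann.enhancer_catalogs["synthetic_enhancers"],
    }
    enr_results = []
    groups: Dict[str, Set[BinKey]] = {}
    for cancer in ("A", "B"):
        for direction in ("hyper", "hypo"):
            groups[f"{cancer}_{direction}"] = recurrent[cancer].bins(direction)
    for gid, bins in groups.items():
        ivset = IntervalSet.from_bins(bins)
        enr_results.extend(en.feature_enrichment(ivset, features, bg, group_id=gid))
    en.enrichment_table(enr_results).to_csv(
        out / "feature_enrichment.tsv", sep="\t", index=False
    )
    hmm_results = []
    for gid in ("A_hyper", "A_hypo"):
        hmm_results.extend(
            en.chromhmm_enrichment(
                IntervalSet.from_bins(groups[gid]), genome.stack18, bg, group_id=gid
            )
        )
    en.enrichment_table(hmm_results).to_csv(
        out / "chromhmm_enrichment.tsv", sep="\t", index=False
    )
    manifest.record(
        "enrichment", out / "feature_enrichment.tsv", out / "chromhmm_enrichment.tsv"
    )
    manifest.summary["feature_enrichment"] = {
        f"{r.group_id}:{r.feature_id}": r.enrichment for r in enr_results
    }

    # ---- stage 4: ceDMRs, breakdown, gene assignment -----------------------
    enhancer_union = rg.active_enhancer_union(genome.stack18)
    promoter_union = rg.promoter_like_union(ann.genes, genome.stack18, ann.chrom_sizes)
    ce_sets: Dict[str, rg.CeDMRSet] = {}
    breakdown: Dict[str, Dict[str, float]] = {}
    assignments: Dict[str, rg.GeneAssignment] = {}
    for gid, bins in groups.items():
        merged = rg.merge_consecutive(sorted(bins))
        ce = rg.classify_ce_dmrs(merged, promoters_ext, enhancer_union, direction=gid)
        ce_sets[gid] = ce
        breakdown[gid] = rg.regulatory_breakdown(merged, promoter_union, enhancer_union)
        assignments[gid] = rg.assign_to_gene(ce.dmrs, ann.genes)
    pd.DataFrame(breakdown).T.to_csv(out / "regulatory_breakdown.tsv", sep="\t")
    ce_rows = [
        {"group": gid, "n_input": ce.n_input, "n_promoter_discarded": ce.n_promoter_discarded,
         "n_ce_dmrs": len(ce.dmrs)}
        for gid, ce in ce_sets.items()
    ]
    pd.DataFrame(ce_rows).to_csv(out / "ce_dmrs.tsv", sep="\t", index=False)
    manifest.record("regulatory", out / "regulatory_breakdown.tsv", out / "ce_dmrs.tsv")
    manifest.summary["regulatory_breakdown"] = breakdown
    manifest.summary["n_ce_dmrs"] = {g: len(c.dmrs) for g, c in ce_sets.items()}

    # ---- stage 5: gene-set (pseudo-TSG) promoter overlap test --------------
    tsg_universe = sorted({g.gene_id for g in ann.genes})[: max(60, config.n_genes // 4)]
    core = rg.define_promoters(
        [g for g in ann.genes if g.gene_id in set(tsg_universe)], "core_1kb", ann.chrom_sizes
    )
    tsg_sets = {
        cancer: core.genes_overlapping(
            _bins_to_intervals(recurrent[cancer].bins("hyper"))
        )
        for cancer in ("A", "B")
    }
    geneset_test = rg.geneset_regulatory_overlap(tsg_sets, tsg_universe)
    with open(out / "tsg_overlap_test.json", "w") as fh:
        json.dump(
            {
                "universe_size": geneset_test.universe_size,
                "set_sizes": geneset_test.set_sizes,
                "observed": geneset_test.observed,
                "log10_p": geneset_test.test.log10_p,
            },
            fh,
            indent=2,
        )
    manifest.record("geneset", out / "tsg_overlap_test.json")
    manifest.summary["tsg_overlap_log10_p"] = geneset_test.test.log10_p

    # ---- stage 6: expression integration -----------------------------------
    hyper_assigned = sorted(
        {gid for gid, _ in assignments["A_hyper"].assignments.values()}
    )
    planted_fc = {g: -2.0 for g in hyper_assigned[:20]}
    gene_ids = [g.gene_id for g in ann.genes]
    expr, expr_groups = plant_expression(config, gene_ids, planted_fc)
    fc_results, missing = em.fold_change(expr, expr_groups, list(planted_fc))
    pd.DataFrame(
        [
            {"gene": r.gene, "mean_tumor": r.mean_tumor, "mean_normal": r.mean_normal,
             "log2_fc": np.nan if r.log2_fold_change is None else r.log2_fold_change}
            for r in fc_results
        ]
    ).to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    manifest.record("expression", out / "fold_changes.tsv")
    fcs = [r.log2_fold_change for r in fc_results if r.log2_fold_change is not None]
    manifest.summary["mean_planted_log2_fc"] = float(np.mean(fcs)) if fcs else None

    # ---- stage 7: motif presence + clustering ------------------------------
    ce_labels = [f"{d.chrom}:{d.start}-{d.end}" for d in ce_sets["A_hyper"].dmrs][:200]
    motif_table, hit_matrix, tf_to_motifs = plant_motifs(config, ce_labels)
    kept = em.filter_enriched_motifs(motif_table, q_max=0.05)
    cut = max(2.0, 0.5 * float(np.sqrt(len(ce_labels))))
    cluster = em.cluster_motif_matrix(hit_matrix, cut_height=cut)
    motif_table.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
    with open(out / "motif_clusters.json", "w") as fh:
        json.dump({str(k): v for k, v in cluster.clusters.items()}, fh, indent=2)
    manifest.record("motifs", out / "motif_enrichment.tsv", out / "motif_clusters.json")
    manifest.summary["n_enriched_motifs"] = int(len(kept))
    manifest.summary["n_motif_clusters"] = len(cluster.clusters)

    # ---- stage 8: TE analyses ----------------------------------------------
    hypo_ivs = _bins_to_intervals(groups["A_hypo"])
    te_overlap = te.te_dmr_overlap(hypo_ivs, ann.te_table)
    cascade = te.te_regulatory_cascade(
        te_overlap.te_sub_regions, promoters_ext, genome.stack18
    )
    subfam = te.subfamily_enrichment(hypo_ivs, ann.te_table, genome.grid)
    pd.DataFrame(
        [
            {"subfamily": r.subfamily, "n_te": r.n_te, "n_dmr": r.n_dmr,
             "N_te": r.big_n_te, "N_all": r.big_n_all, "E_s": r.e_s}
            for r in subfam
        ]
    ).to_csv(out / "te_subfamily_enrichment.tsv", sep="\t", index=False)
    meth_tables, meth_groups = plant_te_methylation(config, ann.te_table)
    target_copies = [
        t for t in ann.te_table if t.subfamily == config.hypomethylated_subfamily
    ]
    per_sample_means = {}
    for sid, table in meth_tables.items():
        cm = te.copy_methylation(target_copies, table, min_coverage=5)
        vals = [v for v in cm.values() if v is not None]
        per_sample_means[sid] = float(np.mean(vals)) if vals else np.nan
    pd.Series(per_sample_means).to_csv(out / "te_copy_methylation.tsv", sep="\t")
    manifest.record(
        "te", out / "te_subfamily_enrichment.tsv", out / "te_copy_methylation.tsv"
    )
    manifest.summary["te_fraction_hypo_with_te"] = te_overlap.fraction_with_te
    manifest.summary["te_cascade"] = cascade
    manifest.summary["te_subfamily_e_s"] = {r.subfamily: r.e_s for r in subfam}
    manifest.summary["te_meth_by_group"] = {
        grp: float(
            np.nanmean([m for s, m in per_sample_means.items() if meth_groups[s] == grp])
        )
        for grp in ("tumor", "normal")
    }

    # ---- stage 9: array coverage + region shift ----------------------------
    probe_set = ann.probe_manifests["synthetic"]
    dmr_groups_iv = {gid: _bins_to_intervals(bins) for gid, bins in groups.items()}
    coverage = ac.probe_coverage(dmr_groups_iv, probe_set)
    pd.Series(coverage.fractions).to_csv(out / "array_coverage.tsv", sep="\t")
    betas, beta_groups, patients = plant_betas(
        config, genome, groups["A_hyper"], groups["A_hypo"]
    )
    collapsed = ac.collapse_patients(betas, patients)
    shift_results = {}
    for direction, sign in (("hyper", 1), ("hypo", -1)):
        try:
            means = ac.region_methylation(dmr_groups_iv[f"A_{direction}"], collapsed, probe_set)
        except ValueError:
            continue
        tumor = [means[s] for s in means.index if beta_groups[patients_inv(patients)[s]] == "tumor"]
        normal = [means[s] for s in means.index if beta_groups[patients_inv(patients)[s]] == "normal"]
        shift_results[direction] = ac.group_shift_test(tumor, normal, expected_sign=sign)
    with open(out / "region_shift_tests.json", "w") as fh:
        json.dump({d: asdict(r) for d, r in shift_results.items()}, fh, indent=2)
    manifest.record("array", out / "array_coverage.tsv", out / "region_shift_tests.json")
    manifest.summary["array_coverage"] = coverage.fractions
    manifest.summary["region_shift"] = {
        d: {"p": r.p_value, "sign_matches": r.sign_matches} for d, r in shift_results.items()
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"seed": manifest.seed, "stages": manifest.stage_outputs,
             "summary": manifest.summary},
            fh,
            indent=2,
            default=float,
        )
    return manifest


def patients_inv(patients: Dict[str, str]) -> Dict[str, str]:
    """patient id -> sample id (patients are 1:1 with samples in fixtures)."""
    return {p: s for s, p in patients.items()}


def summary_tables(manifest: RunManifest) -> Dict[str, pd.DataFrame]:
    """Reload every stage table written by ``run_pipeline``."""
    out = Path(manifest.out_dir)
    tables = {}
    for stage, paths in manifest.stage_outputs.items():
        for p in paths:
            p = Path(p)
            if p.suffix == ".tsv":
                tables[p.stem] = pd.read_csv(p, sep="\t")
    return tables
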