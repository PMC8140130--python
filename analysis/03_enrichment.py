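#!/usr/bin/env python
"""Genomic-feature and chromatin-state enrichment of the DMR groups.

For each DMR group (cancer x direction), computes the fraction of DMR
nucleotides overlapping each annotation category, divides by the analogous
background fraction, and repeats the computation per chromatin state and
epigenome on the 18-state segmentation stack.
"""

from pathlib import Path

from dmrcompare import enrichment as en
from dmrcompare import dmr_compare as dc
from dmrcompare.fixtures import FixtureConfig, generate_genome, plant_dmrs
from dmrcompare.genome_model import IntervalSet
from dmrcompare.regulatory import define_promoters

OUT = Path(__file__).resolve().parent.parent / "results" / "03_enrichment"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = FixtureConfig(seed=SEED)
    genome = generate_genome(cfg)
    planted = plant_dmrs(cfg, genome)
    recurrent = {
        c: dc.call_recurrent(planted.calls[c], cfg.n_samples[c], cfg.min_support[c], c)
        for c in ("A", "B")
    }

    ann = genome.annotation
    features = {
        "promoter_2p5kb": define_promoters(ann.genes, "extended_2p5kb",
                                           ann.chrom_sizes).interval_set(),
        "cpg_island": ann.cpg_islands,
        "gene_body": IntervalSet.from_intervals(g.body for g in ann.genes),
        "te": IntervalSet.from_intervals(t.interval for t in ann.te_table),
        "enhancer_catalog": ann.enhancer_catalogs["synthetic_enhancers"],
    }

    results = []
    for cancer in ("A", "B"):
        for direction in ("hyper", "hypo"):
            gid = f"{cancer}_{direction}"
            dmrs = IntervalSet.from_bins(recurrent[cancer].bins(direction))
            results.extend(
                en.feature_enrichment(dmrs, features, genome.background, group_id=gid)
            )
    table = en.enrichment_table(results)
    table.to_csv(OUT / "feature_enrichment.tsv", sep="\t", index=False)

    print("nucleotide-level enrichment over genomic features:")
    for _, row in table.iterrows():
        print(f"  {row['group']:8s} {row['feature']:18s} "
              f"dmr={row['dmr_fraction']:.3f} bg={row['background_fraction']:.3f} "
              f"enrichment={row['enrichment']:.2f}")

    hmm = []
    for gid in ("A_hyper", "A_hypo"):
        cancer, direction = gid.split("_")
        dmrs = IntervalSet.from_bins(recurrent[cancer].bins(direction))
        hmm.extend(en.chromhmm_enrichment(dmrs, genome.stack18, genome.background,
                                          group_id=gid))
    hmm_table = en.enrichment_table(hmm)
    hmm_table.to_csv(OUT / "chromhmm_enrichment.tsv", sep="\t", index=False)

    top = (hmm_table.dropna(subset=["enrichment"])
           .groupby(["group", "feature"])["enrichment"].mean()
           .groupby("group", group_keys=False).nlargest(3))
    print("top chromatin states by mean enrichment across epigenomes:")
    print(top.to_string())
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
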