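#!/usr/bin/env python
"""Generate the synthetic two-cancer methylation cohort and write its inputs.

Builds the default synthetic genome (3 x 5 Mb, islands near TSSs, 18-/15-state
segmentations, TE subfamilies, promoter-biased probes), constructs the
background bin universe, and plants per-sample DMR calls for the two
pseudo-cancers A and B with a shared fraction of 0.15.  Everything downstream
(scripts 02-07) regenerates the identical cohort from the same seed.
"""

from pathlib import Path

import pandas as pd

from dmrcompare.fixtures import FixtureConfig, generate_genome, plant_dmrs
from dmrcompare import io as dio

OUT = Path(__file__).resolve().parent.parent / "results" / "01_cohort"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = FixtureConfig(seed=SEED)
    genome = generate_genome(cfg)
    planted = plant_dmrs(cfg, genome)

    ann = genome.annotation
    dio.write_gene_models(ann.genes, OUT / "genes.tsv")
    dio.interval_set_to_bed(ann.cpg_islands, OUT / "cpg_islands.bed")
    dio.write_te_table(ann.te_table, OUT / "te_table.tsv")
    dio.write_probe_manifest(ann.probe_manifests["synthetic"], OUT / "probes.tsv")
    dio.write_segmentation(genome.stack18, OUT / "segmentation_18state")

    rows = [
        {"cancer": cancer, "sample": c.sample_id, "chrom": c.bin[0],
         "start": c.bin[1], "direction": c.direction}
        for cancer in ("A", "B")
        for c in planted.calls[cancer]
    ]
    pd.DataFrame(rows).to_csv(OUT / "per_sample_dmr_calls.tsv", sep="\t", index=False)
    pd.DataFrame(genome.background.bins, columns=["chrom", "start"]).to_csv(
        OUT / "background_bins.tsv", sep="\t", index=False
    )

    print(f"genome: {sum(ann.chrom_sizes.values()):,} bp over {len(ann.chrom_sizes)} chromosomes")
    print(f"background universe: {genome.background.n_bins:,} eligible 500-bp bins")
    print(f"genes: {len(ann.genes)}, TE copies: {len(ann.te_table)}, "
          f"probes: {ann.probe_manifests['synthetic'].n_probes}")
    for cancer in ("A", "B"):
        n_hyper = len(planted.consensus[cancer]["hyper"])
        n_hypo = len(planted.consensus[cancer]["hypo"])
        print(f"cancer {cancer}: planted {n_hyper} hyper + {n_hypo} hypo consensus bins, "
              f"{len(planted.calls[cancer])} per-sample calls")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
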