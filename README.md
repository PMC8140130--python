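# dmrcompare

Comparative analysis of DNA-methylation abnormalities in two cancer types,
starting from per-sample differentially methylated region (DMR) calls at
500-bp resolution.

Tumors of very different lineage — an esophageal adenocarcinoma-like and a
glioblastoma-like cohort are the motivating case — share a surprising amount
of their methylation pathology: focal hypermethylation concentrated at
promoters and active enhancers, broad hypomethylation biased toward
intergenic space and transposable elements, and an overlap between the two
cancers' DMR sets far above chance. `dmrcompare` implements the analysis
chain that establishes these observations, as a tested, reusable library
plus a set of narrative analysis scripts, exercised end-to-end on a seeded
synthetic-genome generator so the whole pipeline runs offline.

## What it computes

Let the genome be tiled into 500-bp bins and let *N* be the number of
eligible background bins (≥ 1 CpG, MeDIP/MRE signal in ≥ 1 sample, not
blacklisted, not at a chromosome end). The pipeline provides:

- **Recurrent DMR calling** — a bin is a consensus DMR of a cancer when
  called in the same direction in ≥ `min_support` samples; bins meeting the
  threshold in both directions are dropped.
- **Shared/unique categorization and overlap significance** — sharing
  requires identical bin *and* direction. With *n_A*, *n_B* consensus DMRs
  and *k* shared, the expected sharing under independence is
  *E* = (*n_A*/*N*)·*n_B*, and significance is the upper-tail
  hypergeometric probability P(X ≥ k), X ~ Hypergeom(*N*, *n_A*, *n_B*),
  computed entirely in log space (log-gamma + logsumexp) so that tails far
  below the double-precision minimum (log₁₀ p ≈ −4300 at cohort scale)
  remain finite. The hyper:hypo count ratio is reported half-up-rounded to
  three decimals.
- **Enrichment** — the fraction of DMR nucleotides inside a feature divided
  by the analogous background fraction, per genomic category and per
  (chromatin state × epigenome) of an 18-/15-state segmentation stack;
  signal-track ratios; state-presence matrices and peak-group occupancy
  with a Welch *t* comparison of per-epigenome fractions.
- **ceDMRs and gene assignment** — consecutive bins merged, merged DMRs
  overlapping 2.5-kb promoters discarded, the remainder kept when they touch
  an active-enhancer state (9_EnhA1/10_EnhA2) in ≥ 1 epigenome, then
  assigned to the gene with the nearest TSS (edge distance, ≤ 500 kb).
  Gene-set overlap (e.g., tumor-suppressor promoters hypermethylated in both
  cancers) uses the same hypergeometric kernel over a gene universe.
- **TE analysis** — per-subfamily enrichment
  E_s = (n_TE/n_DMR)/(N_TE/N_all) over the full bin grid, a sequential
  regulatory cascade for DMR-overlapped TE pieces, and per-copy methylation
  means over ≥ 5× CpGs.
- **Expression and motifs** — log₂ fold change of group-mean RPKM,
  TF filtering by BH-corrected directional Welch tests, motif-table
  filtering, and complete-linkage clustering of binary DMR × TF motif-hit
  matrices cut at a configurable height.
- **Array coverage** — DMR identifiability (≥ 1 probe inside the bin,
  half-open), patient-level beta collapsing, region-mean methylation and
  directional shift tests.

## Layout

```
src/dmrcompare/      library: one module per pipeline stage
  genome_model.py    coordinates, interval engine, bin grid, background universe
  io.py              BED/TSV readers and writers with validation
  stats.py           log-space hypergeometric kernel
  dmr_compare.py     recurrence, categories, ratios, overlap tests
  enrichment.py      feature/chromHMM/signal enrichment, presence, occupancy
  regulatory.py      promoters, merging, ceDMRs, gene assignment, gene sets
  te_methylation.py  TE overlap, cascade, subfamily enrichment, copy methylation
  expression_motifs.py  fold changes, TF filters, motif clustering
  array_coverage.py  probe coverage, beta collapsing, shift tests
  fixtures.py        seeded synthetic-cohort generator
  reporting.py       end-to-end orchestration
analysis/            numbered narrative drivers (01_simulate_cohort.py ...)
tests/               pytest suite incl. oracle and acceptance tests
scripts/acceptance.py  recomputes the headline quantities, writes JSON
docs/methods.md      model, parameters, generator assumptions, limitations
```

## Worked example

Running the analysis chain on the default synthetic cohort (seed 7):

```
$ python analysis/01_simulate_cohort.py
genome: 15,000,000 bp over 3 chromosomes
background universe: 25,885 eligible 500-bp bins
cancer A: planted 1400 hyper + 700 hypo consensus bins, 5759 per-sample calls
cancer B: planted 900 hyper + 450 hypo consensus bins, 6218 per-sample calls

$ python analysis/02_call_and_compare_dmrs.py
recurrence filtering (min 2 of n samples):
  cancer A: 2178 called bins -> 2050 recurrent (ratio hyper:hypo = 1.997)
  cancer B: 1493 called bins -> 1350 recurrent (ratio hyper:hypo = 2.000)
shared hyperDMRs: observed 357 vs expected 47.5 -> log10 p = -225.9
shared hypoDMRs: observed 130 vs expected 11.9 -> log10 p = -97.6
```

Reading: recurrence trims singleton noise calls; the recovered hyper:hypo
ratio matches the planted 2:1 mixture; and because 15% of cancer B's bins
were copied from cancer A, the observed sharing (357 hyper bins) exceeds the
independence expectation (47.5) at log₁₀ p ≈ −226 — the synthetic analogue
of the real cohorts' shared methylation signature. Scripts 03–07 continue
through enrichment (promoter enrichment 6.4× for hyperDMRs vs 1.5× for
hypoDMRs), ceDMR classification, TE subfamily enrichment (the planted
hypomethylated subfamily reaches E_s ≈ 20 among hypoDMRs and drops from
β ≈ 0.80 to ≈ 0.36 in tumor pseudo-samples), expression-fold-change
recovery, motif clustering, and the array-coverage asymmetry (hyperDMRs
≈ 19% identifiable on the promoter-biased panel vs ≈ 9% for hypoDMRs).

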