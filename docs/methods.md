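# Methods

## Coordinate model and the background universe

All coordinates are 0-based half-open (BED convention); any 1-based source
(e.g., the Illumina manifest CSV dialect) is converted at the reader
boundary. The genome is tiled into 500-bp bins anchored at coordinate 0;
trailing partial windows are dropped rather than truncated, so every bin has
identical width and bp↔bin conversions are exact. Readers reject records
with `start >= end`, the signature of 1-based or end-inclusive input.

The background universe — the *N* of every enrichment denominator and
hypergeometric test — keeps a bin iff it (1) is not among the first/last
bin of its chromosome ("chromosome ends" are not otherwise defined upstream;
one bin per end is the minimal reading, and the count is a parameter of
`build_background`), (2) is not blacklisted (the blacklist is consumed as a
precomputed bin set, not recomputed from mappability), (3) contains ≥ 1 CpG,
(4) carries MeDIP and/or MRE signal in ≥ 1 sample (presence, not counts),
and (5) is not on an excluded chromosome (chrY, plus chrX for cohorts with
sex-confounded samples).

## Recurrence and the overlap test

A consensus DMR requires the same direction of change in ≥ `min_support`
distinct samples (default 2). A bin whose hyper- and hypo-support both meet
the threshold is contradictory at the consensus level and is dropped with a
warning; a single sample carrying both directions for one bin is treated as
a malformed input and raises.

Sharing between cancers requires identical bin and identical direction. The
expected number of shared DMRs under independence is
(*n_A*/*N*)·*n_B*; significance is P(X ≥ k) for
X ~ Hypergeom(*N*, *n_A*, *n_B*), i.e., the survival function evaluated at
k−1 (matching the `phyper(..., lower.tail=FALSE)` convention with x−1). The
tail is accumulated in log space from log-gamma binomial terms via
logsumexp. At cohort scale the result is log₁₀ p ≈ −4296 for shared
hypermethylation — thousands of orders of magnitude below the smallest
positive normal double — so results carry `log10_p` plus an explicit
`p_underflows_double` flag instead of a raw probability. The kernel is
verified against exact rational arithmetic (populations ≤ 30, 12
significant digits), against an exhaustive enumeration of draws, and
against `scipy.stats.hypergeom` at moderate tails; scipy is a cross-check
only, never the implementation.

The hyper:hypo ratio is rounded half-up to 3 decimals (`Decimal`
arithmetic), matching how such ratios are conventionally printed; banker's
rounding would differ on boundary cases.

## Enrichment

Feature enrichment is a ratio of nucleotide coverage fractions: the fraction
of DMR bp inside the feature over the fraction of background bp inside the
feature. Interval sets are unioned internally before intersection, so
multiply-covered nucleotides count once. Feature categories are not mutually
exclusive and fractions may sum above 1. Chromatin-state enrichment applies
the same computation per (state, epigenome). DMR groups enter enrichment as
unmerged 500-bp bins; merging is applied only on the ceDMR pathway.

Signal enrichment treats uncovered nucleotides as 0 (bigWig-style
mean-signal semantics for control-normalized tracks). State/peak presence
uses a ≥ 1 bp overlap threshold (configurable); group comparisons of
per-epigenome presence fractions use a two-sided Welch *t* test — the
conservative default where the variant is not otherwise specified — with a
Student variant available.

## Promoters, ceDMRs and gene assignment

Promoter windows are strand-oriented around each transcript's TSS: 1-kb core
(±500 bp) and 2.5-kb extended (−2000/+500 bp), clipped at chromosome bounds;
all transcripts are kept as separate records and collapse to gene level by
any-transcript logic. The TSS is `body.start` on + and `body.end` on −
strands.

ceDMR classification fixes the filter order: merge consecutive same-direction
bins, discard merged DMRs overlapping any extended promoter, then require
≥ 1 bp overlap with the union of active-enhancer states (9_EnhA1/10_EnhA2)
across epigenomes. The two filters do not commute in general; the discard
step runs first.

Nearest-TSS assignment measures edge distance (0 when the TSS lies inside
the region), breaks ties lexicographically by gene id with a warning, and
leaves regions unassigned beyond 500 kb. The four-way regulatory breakdown
(both / promoter-only / enhancer-only / neither) uses as its promoter set
the union of extended gene-model windows and TSS-like states 1–4 in ≥ 1
epigenome, and is a strict partition summing to 100%.

Gene-set overlap tests (e.g., tumor-suppressor promoters hypermethylated in
both cancers) reuse the hypergeometric kernel with the gene universe as
population; the universe is gene-level — any transcript's promoter hit
counts its gene once.

## TE analysis

Subfamily enrichment E_s = (n_TE/n_DMR)/(N_TE/N_all) counts, for the
denominator, full-grid 500-bp windows overlapped ≥ 1 bp by the subfamily —
the full grid rather than the filtered background, since the reference rate
is genome-wide occupancy (the choice is exposed in the function's grid
argument). The regulatory cascade for DMR-overlapped TE pieces is strictly
sequential (genic promoter → TSS states → active-enhancer states → other),
so tier bp percentages sum to exactly 100. Per-copy methylation is the
unweighted mean over contained CpGs with coverage ≥ 5×; copies with no
passing CpG are reported missing, and duplicated table rows are
de-duplicated first. Simple repeats, low-complexity and satellite records
are removed at the reader.

## Expression and motifs

Fold change is log₂ of the ratio of arithmetic group means of RPKM; zero or
missing denominators are reported as undefined rather than clamped. TF
normalization drops samples at RPKM ≤ 1, log₂-transforms and z-scores with
the sample (n−1) standard deviation (population sd available via `ddof`).
The TF expression filter runs a two-sided Welch *t* per TF on raw RPKM (a
log₂ switch is provided), adjusts with Benjamini–Hochberg across tested TFs
and retains a TF only when the adjusted p ≤ α **and** the group-mean
difference has the direction required by the DMR polarity (loss for
ce-hyperDMRs, gain for ce-hypoDMRs) — so no p-value, however small, retains
a TF moving the wrong way.

Motif-presence clustering operates on a binary DMR × TF matrix: Euclidean
distances between columns, complete linkage, tree cut at a configured
height; groups with > 1 TF are clusters, each reported with the DMR rows
hitting ≥ 1 member motif. Cut heights are per-analysis configuration, not
constants of the library. Motif→TF mapping and hit locations are inputs; no
motif database is bundled, and the only sequence handling anywhere is the
toy consensus scanner inside the synthetic generator.

## Array coverage

A DMR is identifiable on a platform iff ≥ 1 probe coordinate falls in
[start, end). Same-patient samples are averaged per probe before group
comparisons; missing betas are ignored pairwise, never imputed. Region
methylation is the unweighted mean beta over probes inside the region set,
per sample; the tumor-vs-normal shift uses a two-sided Welch *t* by default
with a rank-sum variant available, plus a flag for whether the observed
direction matches expectation.

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes, at
1/200 genome scale (3 × 5 Mb, ~30,000 bins — sized so every analysis and
the full test suite complete in seconds while leaving hundreds to thousands
of events per category):

- 360 genes placed uniformly; CpG islands seeded at 70% of TSSs plus random
  islands; CpG density 0.08/bp inside islands vs 0.004/bp outside (≈ 2 per
  500-bp bin, so the ≥ 1-CpG background filter actually bites);
- segmentations per epigenome built from forced segments — TSS states at
  promoters (80% of epigenomes per gene, flanked by TssFlnk/U/D states) and
  active-enhancer states at 400 shared enhancer loci (50% inclusion per
  epigenome) — with gaps filled by an exponential-dwell chain over
  non-regulatory states (mean 2 kb, 10 kb for quiescent). TSS-proximal
  states never appear in random fill, so state unions mean what they mean in
  real segmentation stacks;
- four TE subfamilies with uniformly placed copies; one subfamily (MERX)
  designated hypomethylated in tumors (β 0.35 vs 0.80, Poisson-10 coverage);
- 4,000 probes, 70% drawn inside islands (the promoter bias that produces
  the real platforms' coverage asymmetry);
- DMRs planted per cancer and direction by a category mixture over
  promoter/enhancer/TE/intergenic bins (hyper: 45/30/5/20%; hypo:
  8/12/35/45%), cancer B copying 15% of cancer A's bins per direction;
  per-sample calls derived from the consensus with 10% dropout plus 30
  singleton noise calls per sample, so recurrence filtering is exercised;
  sample sizes 3 (A) and 5 (B) with min-support 2;
- lognormal expression (log₂ mean 3, sd 1.2, per-sample noise sd 0.4) with
  planted fold changes; betas low in islands (0.15) and high elsewhere
  (0.80) with planted ±0.25 tumor shifts starting from the
  direction-appropriate baseline (hypermethylation from the low baseline,
  hypomethylation from the high one, so shifts are not clipped at [0, 1]);
- toy 8-mer consensus motifs embedded in 200-bp synthetic DMR sequences at
  60% (planted-enriched TFs) vs 10% (background) per DMR.

One global seed fans out into fixed per-component child streams
(`numpy.random.SeedSequence.spawn`), so regenerating one layer never
perturbs another. For the overlap-test calibration, planting supports a
uniform mode that ignores the category mixture: under structured planting
both cancers concentrate in the same annotation categories, which inflates
overlap relative to the uniform-background null by construction — a real
property of the science, not a defect of the test.

What passing tests on this cohort do show: correctness of every counting,
filtering and testing rule, calibration of the overlap test under a uniform
null, and recovery of planted effect sizes through the full chain. What
they do not show: robustness to real-data pathologies the generator omits —
copy-number-driven coverage artifacts, batch effects in arrays and RNA-seq,
assembly gaps, polymorphic TE insertions, and correlated per-sample noise.

## Numerical choices and degenerate inputs

Identical-group *t* tests return statistic 0, p = 1 (scipy's NaN is mapped).
Enrichment against a feature with zero background overlap is undefined
(None), not infinite. Empty DMR sets are errors where a fraction would be
0/0. The hypergeometric kernel returns log₁₀ p = 0 exactly when the
observed count is at or below the distribution's support minimum. Ratio
rounding uses `decimal` half-up. Interval sets merge abutting intervals, so
`merge_consecutive` is idempotent and bp-preserving by construction.

## Known limitations

- The per-sample DMR caller itself is out of scope; its calls are inputs.
- Motif enrichment statistics against a real genomic background, GO/ontology
  enrichment and genome-browser rendering are external-tool territory; the
  pipeline produces the region sets those tools consume (BED export of
  merged ceDMR sets is the documented hand-off point).
- The synthetic scale (≈ 26,000 background bins vs ≈ 5.2 million in a real
  cohort) means cohort-scale tail magnitudes (log₁₀ p ≈ −4300) arise only
  in the direct computation on published counts, not in synthetic runs.
- No liftover, no FASTA handling beyond the fixtures' toy scanner.
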