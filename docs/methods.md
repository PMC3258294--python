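# Methods

This note documents the models and procedures estdex implements, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions adopted where the procedure
admitted more than one reading.

## Study design the package assumes

One pooled cDNA library per photoperiod treatment (DI: short-day,
diapause-inducing; NDI: long-day, non-diapause-inducing), sequenced without
biological replication; a contig/singleton ("EST") set produced by an
external assembler; homology searches against a ladder of reference
databases supplied as 12-column tabular alignments; and a qPCR experiment
(5 biological × 3 technical replicates per treatment) as the validation
benchmark. Nothing in the package runs an aligner or assembler — alignment
tables are inputs.

## Read QC

Filters run in a fixed order — ambiguous bases, exact-sequence duplicates,
mean Phred < 25, contaminant homology, poly-A/T trimming, 50 bp floor — and
the per-step tallies are defined by that order (a read carrying two defects
is charged to the first filter that catches it). Boundary conventions:
mean quality exactly 25 survives ("lower than 25" removes strictly below);
a 50 bp read survives ("shorter than 50 bp"); contaminant hits remove a
read when e-value ≤ 1e-25 — significant matches have *small* e-values, so
the screen is on ≤. Duplicate means exact full-sequence identity with the
first occurrence kept: pyrosequencing's artificial duplicates have no
published criterion, and exact identity is conservative and deterministic.
Poly-A/T trimming is our own rule (the tool historically used for this step
is unpublished): a terminal run of ≥ 10 A (3') or T (5') counting at most
one interior non-matching base is removed, qualities in register; both
knobs sit in `QcConfig`. The full pass is idempotent and conserves reads
(`remaining + Σ removed = input`).

N50 is the smallest length L such that sequences of length ≥ L contain at
least half the summed bases, computed by descending cumulative sum.

## Annotation cascade

Tiers are ordered by taxonomic distance with e-value ceilings 1e-10
(conspecific mRNA; congeneric transcripts, genome, peptides), 1e-5
(congeneric-family and dipteran peptides), 1e-4 (nematode peptides), 1e-3
(Swiss-Prot). An EST is assigned within the *first* tier holding a hit
under its ceiling; within a tier the best hit has the lowest e-value, ties
broken by highest bitscore, residual ties by subject id. We deliberately do
not pick a global lowest e-value across tiers: e-values from nucleotide and
translated searches against databases of different sizes are not
commensurable, and the first-qualifying-tier walk is what produces the
taxonomic stratification the tier table is for. The residual subject-id
tie-break exists only to make assignment a function of its inputs.

The gene-accumulation curve permutes the read→gene hit list (default 1,000
permutations; pipeline runs use 200 for speed) and averages the cumulative
count of newly seen genes per read rank. Its endpoint equals the number of
distinct genes for every permutation, which is the main correctness handle.

## Redundancy reduction and trimming

ESTs assigned to the same reference gene form a group; one representative
survives. For tiers with an identity cutoff (85% for the conspecific and
congeneric nucleotide tiers, 70% for congeneric peptides), the longest
alignment among members at or above the cutoff wins; if none reaches it,
the highest identity wins. For distant tiers (cutoff 0) the highest
identity wins among alignments ≥ 50 bp. Ties fall back to higher identity
(or longer alignment), then est id — the source procedure states no tie
rule, and determinism is required for testing.

Genomic-tier hits pass only when strictly more than half of the *aligned
genomic span* (subject coordinates, interval union over annotated mRNA)
falls inside mRNA; the denominator is the aligned span because unaligned
EST tails have no genomic placement.

The winner is trimmed to its alignment's query coordinates (min/max
normalized, so minus-frame translated hits trim the same span), always on
the forward strand — the output is a nucleotide EST resource in
source orientation. The 50 bp minimum applies to the *trimmed* product
(the stricter of the two possible readings); groups whose winner trims
shorter are dropped with a logged reason.

## Differential expression

With one library per condition, significance comes from the exact binomial
test conditional on each gene's two-library total: x_DI ~ Binomial(k, p0)
under the null, p0 = N_DI/(N_DI+N_NDI) with effective library sizes N. The
two-sided p sums every outcome whose point probability does not exceed the
observed one (minimum-likelihood convention, as in SAGE-style count tests —
note this differs from doubling the smaller tail). BH step-up correction is
applied across genes; calls require adjusted p < 0.001.

Effective sizes come from one of two normalizations:

* **TMM** — implemented from first principles and cross-checked in the test
  suite against the canonical R implementation on the same matrix. The
  reference library is the one whose upper quartile of count proportions is
  closest to the mean upper quartile. Per-gene M (log2 proportion ratio)
  and A (mean log2 proportion) are computed over genes positive in both
  libraries, the upper and lower 30% of M and 5% of A are discarded, and
  the factor is 2 to the precision-weighted mean of the surviving M values
  (inverse delta-method binomial variances as weights). Factors are
  rescaled to multiply to 1; effective size = raw size × factor. If all M
  are within 1e-6 of zero the factor is exactly 1.
* **RPKM** — count × 10⁹ / (length × library size), with trimmed EST length
  as transcript length; all values are rescaled by a single constant so the
  grand sum equals the original two-library read total (conserved to
  relative error < 1e-9), then rounded to integers for the binomial test
  (which needs integer outcomes), with per-library sums of the rounded
  values as effective sizes.

Fold-change is M = log2((x_DI+0.1)/N_DI) − log2((x_NDI+0.1)/N_NDI); the 0.1
pseudocount exists solely so genes observed in one library keep a finite
fold-change — it never enters the significance test. A is the mean of the
two log2 pseudocount abundances (one of several possible MA-plot
conventions; adopted and documented here). Genes with a zero raw count are
flagged `unique_to` a treatment.

A caveat the test suite makes explicit: rescaling RPKM to pseudo-counts
multiplies each gene's count by ~C/(length × library size). For genes
shorter than average that factor exceeds 1, the pseudo-count's sampling
variance is understated by the same factor, and the binomial test becomes
anti-conservative — on the 2,000-gene benchmark the RPKM path's
false-discovery proportion runs around 0.15 (all false calls short genes)
while the TMM path stays at 0. This is a property of the rescaled-RPKM
significance procedure itself, consistent with its poor specificity against
qPCR in the original comparison; the acceptance test records it as a
failure rather than hiding it.

## qPCR quantification and concordance

Technical replicates are averaged arithmetically per biological replicate;
ΔCt = mean target Ct − geometric mean of the three reference-gene mean Cts
(geometric mean over Ct values, exactly as the procedure is worded);
abundance = 2^−ΔCt. Fold-change = log2(mean DI abundance / mean NDI
abundance). Significance is a pooled-variance two-sample Student's t-test
on per-replicate abundances (Welch available via `equal_var=False`), BH
across genes; zero within-group variance with equal means is flagged
degenerate with p = 1. CV uses the n−1 sample standard deviation (not
specified by the source; stated here).

Concordance treats qPCR as the benchmark: a sequencing positive is TP when
qPCR is significant in the same direction, otherwise FP; a sequencing
negative is TN when qPCR is non-significant, otherwise FN. Sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP) — the standard epidemiological forms,
which are the ones consistent with the published worked example (the
accompanying verbal definition reads differently and is treated as a
wording slip). Directional consistency is the fraction of a call category
whose qPCR fold-change sign matches the prediction. An exclusion list on
the correlation fit mirrors the removal of a paralog-confounded outlier
before regression.

## Synthetic data: what it emulates, what it does not

Generators are deterministic per seed and everything they emit is traceable
through the ground-truth manifest.

* **Reference genes**: random ACGT sequences, lognormal lengths (median
  600 bp, σ_log 0.5, floor 100 bp — transcript-fragment scale), one mRNA
  feature each on a synthetic scaffold; lognormal baseline expression
  (σ 0.6). Planted DE genes get |log2FC| = 2 alternating in direction, with
  expression floored at 2× the median scale so the planted signal sits in
  the well-measured range, as qPCR-verified candidates do in practice.
* **Contigs**: per-gene EST count 1 + Poisson(mean−1), default mean 8.86
  (the redundancy the pooled assembly showed); jittered gene sub-spans plus
  random non-homologous flanks are the "variable ends" trimming removes.
  Hit tables are *constructed* from provenance, not aligned: bitscore grows
  with alignment length × identity, e-value decays exponentially with
  bitscore. This is sufficient because the pipeline consumes tabular hits;
  it does not emulate alignment-score statistics. No-hit and two-gene
  chimeric contigs (each half covering ≤ 60%) exercise the failure paths.
* **Counts**: negative binomial with means ∝ length × expression × library
  depth, DI:NDI depth ratio = skew (default 1.1). Default dispersion is 0
  (Poisson): both libraries draw from one pooled RNA sample, so
  between-library variation is sampling variation — the regime the exact
  binomial test assumes; overdispersion is a parameter for robustness
  experiments, not the default condition. Treatment-unique genes are forced
  exactly when requested.
* **Reads**: substrings of gene sequences with 1% substitution error and a
  uniqueness guard (so only the injected duplicate class collides), one
  defect per read at the requested rates; contaminant reads come with a hit
  table at e-value ≪ 1e-25.
* **Ct tables**: three reference genes whose expected Cts have geometric
  mean exactly at the baseline cycle (so noiseless recovery is an
  identity); target Ct = baseline − log2(true abundance) + N(0, 0.15²)
  per measurement.

Not emulated: flowgram chemistry and homopolymer errors, assembly,
alignment-score statistics, amplification-efficiency variation, and real
biological replicate structure. Passing tests therefore demonstrate
correctness of the *analysis* under its own assumptions, not robustness to
assembler artifacts or qPCR efficiency drift.

## Problem sizes and benchmark conventions

The recovery benchmark uses 2,000 genes, ~600k reads across both libraries,
20 planted DE genes, 10% skew — large enough for stable recall/FDP, small
enough for a desk run. The "tiny" fixture (40 genes, 800 reads) exists for
smoke tests and examples; "paper-like" (300 genes, redundancy mean 8.86,
defect-injected reads) mirrors the study's shape at reduced scale. qPCR
recovery is scored as |estimated − true| / SE with the SE from the
replicate spread of log2 abundances; with 5 biological replicates that
statistic is t₈-distributed, so the collective assertion is mean |z| ≤ 3
and ≥ 90% of targets within 3 SE rather than a max-over-targets bound,
which would fail by chance alone in a large fraction of honest runs.

## Known limitations

* No replicate-aware DE model (by design: the two-library layout has none);
  dispersion estimated from replicates is out of scope.
* The RPKM significance path's short-gene anti-conservativeness, above.
* Isoform validation, GO enrichment, and curated contaminant gene lists are
  out of scope; the viral/bacterial screen is an input exclude list.
* The reducer keeps exactly one EST per gene: genes genuinely novel to the
  focal species (no homology anywhere) are dropped by construction.
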