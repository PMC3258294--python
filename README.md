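# estdex

Post-processing and candidate-gene discovery for *de novo* EST
(expressed sequence tag) transcriptomes of non-model organisms, built around
the two-library design used to study photoperiod-driven diapause induction
in insects: one pooled 454-style cDNA library per photoperiod treatment
(DI = diapause-inducing short days, NDI = non-diapause-inducing long days),
no biological replication at the sequencing level, and qPCR as the
downstream benchmark.

It is aimed at groups who have a contig/singleton set and tabular homology
searches in hand and need the analysis that turns them into a non-redundant,
annotated EST resource with differential-expression calls and an honest
assessment of how well those calls survive qPCR validation.

## What it does

* **Read QC** (`estdex.qc`) — the four cleaning filters (ambiguous bases,
  exact-duplicate artifacts, mean Phred < 25, contaminant homology at
  e-value ≤ 1e-25) plus poly-A/T tail trimming and a 50 bp length floor,
  applied in a fixed order with per-step tallies, N50 and %GC summaries.
* **Tiered annotation** (`estdex.annotation`) — a cascade of reference
  databases (conspecific mRNA → congeneric transcripts/genome/peptides →
  more distant dipterans → Swiss-Prot) with e-value ceilings that relax with
  taxonomic distance. Within the first qualifying tier the best hit wins:
  lowest e-value, ties by highest bitscore. Also the bootstrapped
  gene-accumulation curve (mean cumulative distinct genes per additional
  read over permuted read orders).
* **Redundancy reduction** (`estdex.reduction`) — one representative EST per
  reference gene (longest alignment among members above the tier's identity
  cutoff, otherwise the highest identity), trimmed to its
  homology-supported span; genomic-tier hits are used only when >50% of the
  aligned span lies inside an annotated mRNA.
* **Differential expression** (`estdex.de`) — read-mapping filter (≥95%
  identity, unique mappers only), TMM normalization implemented from first
  principles, RPKM with count-conserving rescaling, an exact binomial test
  on each gene's two counts (minimum-likelihood two-sided convention),
  Benjamini–Hochberg correction, calls at adjusted p < 0.001, and the
  pseudocount fold-change `M = log2((x_DI+0.1)/N_DI) − log2((x_NDI+0.1)/N_NDI)`
  that keeps treatment-unique genes finite.
* **qPCR validation** (`estdex.qpcr`) — modified 2^−ΔΔCt quantification
  against the geometric-mean Ct of three reference genes, pooled-variance
  t-tests with BH correction, CV comparison between treatments, OLS r² of
  platform expression vs qPCR abundance, and the sequencing-vs-qPCR
  confusion summary (sensitivity TP/(TP+FN), specificity TN/(TN+FP),
  directional consistency).
* **Synthetic data** (`estdex.synthetic`) — seeded generators for every
  input with a ground-truth manifest: redundant contig groups per homolog
  with variable ends, constructed hit tables, two skewed count libraries
  with planted DE genes, defect-injected reads, replicated Ct tables.

## Worked example

```bash
estdex simulate --preset tiny --seed 7 --out-dir fixture
estdex run-all  --in-dir fixture --out-dir out --seed 7
```

From `out/run_report.json` (40 genes, 800 reads, 6 planted DE genes plus
2 treatment-unique genes):

```
qc:          removed {ambiguous: 24, duplicate: 24, low_quality: 24,
                      contaminant: 16, short: 16}, remaining 696, N50 361
annotation:  128 contigs assigned, 4 no-hit
reduction:   40 gene groups -> 40 trimmed ESTs, mean 83.9 bp trimmed,
             N50 908 -> 833
de (TMM):    4 DI-up, 5 NDI-up (1 unique to each library)
concordance: TP=6 TN=4 FP=0 FN=0 -> sensitivity 1.0, specificity 1.0
```

The QC tallies equal the injected defect counts recorded in the fixture's
manifest; the reducer keeps exactly one trimmed EST per reference gene; the
DE stage recovers the planted fold-changes: the 9 calls are the 6 planted
DE genes, the 2 forced treatment-unique genes, and one sampling-noise false
positive that is not among the qPCR targets. Within the qPCR target set
every sequencing call is confirmed, so this low-noise fixture's confusion
summary is perfect — real cross-platform comparisons are far from it, which
is exactly what the concordance operation is there to quantify.

Each stage is also available separately (`estdex qc`, `annotate`,
`accumulate`, `reduce`, `de`, `qpcr`, `concord`); run `estdex --help`.

## Layout

```
src/estdex/       qc, annotation, reduction, de, qpcr, synthetic, pipeline, cli
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   models, assumptions, parameter choices, limitations
scripts/          acceptance.py
```
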