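# Methods

## The problem

Adult diffuse gliomas were historically typed and graded from histology alone
(oligodendroglioma, oligoastrocytoma, astrocytoma grades II–III; glioblastoma
grade IV). The 2021 WHO CNS5 taxonomy instead makes molecular markers part of
the diagnosis: IDH1/2 mutation is the primary branch point, 1p/19q codeletion
with IDH mutation defines oligodendroglioma, CDKN2A/B homozygous deletion
lifts an IDH-mutant astrocytoma to grade 4, and any of TERT-promoter
mutation, EGFR amplification, or combined chromosome-7 gain with
chromosome-10 loss makes an IDH-wildtype lower-grade glioma a "molecular
glioblastoma" (grade 4). Histone H3 hotspot substitutions (K27M; G34R) divert
a case to the pediatric-type high-grade entities. Legacy cohorts annotated
under the old scheme therefore carry diagnoses that are wrong under current
criteria, and this package implements the re-annotation plus the downstream
analyses it enables.

## The rule engine

`rules.classify_case` is a total, deterministic function from a case's
feature vector to a CNS5 diagnosis. The decision order is fixed and each
case fires exactly one terminal rule (R0–R3e, listed in the module
docstring); the trace of fired rules is preserved for every case so
reclassification decisions are auditable and regression-testable. Cases with
insufficient molecular data are assigned NA with a machine-readable reason
(`idh_unknown`, `h3_unknown`, `codel_unresolvable`, or `nec` for
IDH-wildtype, H3-wildtype lower-grade tumors without any molecular
glioblastoma feature). The NOS/NEC distinction of clinical practice is
collapsed into this single NA bucket.

Choices where the rules leave room:

- **ATRX shortcut.** ATRX mutation in an IDH-mutant glioma is accepted in
  place of 1p/19q testing *only* when codeletion was not measured; a measured
  codeletion always wins, because codeletion is the defining
  oligodendroglioma marker.
- **Oligodendroglioma grade cap.** CNS5 oligodendroglioma has grades 2–3
  only. An IDH-mutant codeleted case with legacy grade IV is emitted as
  grade 3 with an `oligo_grade_capped` flag rather than inventing a grade 4.
- **Grade imputation.** A definite category with unknown histological grade
  (impossible under the simulator, possible under exhaustive enumeration)
  receives the lowest grade consistent with the category plus a
  `grade_imputed` flag, keeping the function total.
- **Rule ordering for IDH-wildtype cases.** Unknown H3 status yields NA even
  when grade IV histology or molecular glioblastoma features are present;
  the glioblastoma call requires confirmed H3-wildtype status.

## Mutation-status extraction

MAF records are reduced to per-sample hotspot statuses. IDH: any missense
substitution at IDH1 codon 132 or IDH2 codon 172. H3: Lys→Met at position
27/28 in H3-3A (H3F3A), H3C2 (HIST1H3B) or H3C3 (HIST1H3C), and Gly→Arg at
34/35 in H3-3A; both mature-protein and initiator-Met HGVS numbering are
accepted because annotation pipelines disagree on the convention. A sample
present in the MAF with no qualifying row is wildtype; a sample absent from
the MAF has no genomic data and stays unknown — the two must not be
conflated, and `fill_statuses_from_maf` keeps the distinction when resolving
unknown annotation fields. IDH2 R172 is included per the CNS5 definition of
the IDH-mutant branch even though it is a much rarer event than IDH1 R132.

## Pathway activation level

For pathway *p* and sample *s*,

    PAL_p(s) = Σ_n ARR_n · log10(CNR_n(s)) · 100 / Σ_n |ARR_n|,

with CNR the case-to-normal ratio against a reference profile (default: the
gene-wise mean over the cohort, so the cohort average scores 0) and ARR ∈
{−1, −0.5, 0, 0.5, 1} the activator/repressor role of each gene product.
The denominator uses |ARR|: a signed-sum denominator is zero for any
balanced pathway, so the literal signed form is available only behind
`signed_denominator=True` for comparison. A pseudocount (default 1, on
normalized-count scale) guards zero expression; pathway members missing from
the matrix are excluded from both sums and reported as reduced coverage.
Units: +100 PAL corresponds to a tenfold average up-regulation under unit
weights.

## Clustering and subtype assignment

Consensus k-means draws `subsample_fraction` (default 0.8) of the samples
per iteration (default 1000 iterations; tests and the acceptance script use
~60, which is already stable on planted structure), runs k-means on the
subset, and accumulates co-clustering frequencies normalized by
co-sampling counts; the final partition cuts an average-linkage tree of
1 − consensus at k. Everything derives from one seeded generator, so results
are bit-reproducible. Expression matrices are log2(x+1)-transformed and
reduced to the top-variable genes (default 2000) before clustering; on the
linear scale the Euclidean metric is dominated by a handful of highly
expressed genes and class structure is invisible. Methylation betas are
clustered on their native [0, 1] scale after probe-to-gene mean aggregation.
Defaults of k = 5 (expression) and k = 7 (methylation) reflect the cluster
counts commonly reported for these data types; both are configurable.

Agreement between a clustering and a labeling is quantified by the adjusted
Rand index (primary) and normalized mutual information (secondary), with
NA-labelled samples excluded and counted. Multi-aliquot cases may legally
split across clusters; `aliquot_cluster_report` lists them.

Glioblastoma subtypes (Proneural / Classical / Mesenchymal) are assigned by
Ward clustering of samples over the signature genes after log2(x+1) and
per-gene Z-scoring, cutting at k = 3 and labelling each cluster with the
subtype of highest mean standardized signature expression; ties or conflicts
resolve by a maximum-total-score one-to-one assignment. The alternative
transform order (Z-score before log) is mathematically ill-posed for
negative Z-scores; it is retained behind a flag with a positivity shift, and
the default is log-then-Z.

## Survival analytics

Kaplan–Meier medians are the first time the product-limit estimate reaches
0.5, NA when the curve never does; 95% CIs use the exponential-Greenwood
(log-log) transform. Hazard ratios come from univariate Cox
proportional-hazards fits with group indicators against a reference group
(lifelines); zero-event groups are flagged unstable instead of dropped. The
all-pairs comparison reports the log-rank p and the pairwise Cox HR for
every unordered group pair, with star coding at 0.05/0.01/0.001.
Benjamini–Hochberg adjustment is available but off by default, matching how
such pairwise panels are usually reported; the summary statistic is the
percent of significant pairs, rounded to a whole percent. The risk-score
model is a linear combination of gene expressions split at the median score
(ties to the low group), with the high-vs-low HR from a univariate Cox fit.
The published four-gene (FN1, ITGA5, OSMR, NGFR) signature's coefficients
are not distributed here; they load from configuration and tests use
synthetic coefficients.

Biomarker discrimination uses the rank-statistic AUC, U/(n₁n₂) with ties
counted half, equivalent to exhaustive pair counting; significance is the
two-sided Mann–Whitney test. Orientation is always explicit (first-listed
group positive), and an AUC is flagged "useful" above a configurable 0.7
threshold.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is tested.
Generation is truth-first: a latent CNS5 class is drawn per case conditional
on its legacy histology, then observable molecular fields are generated
consistently with the rule engine, so classification recovers the latent
truth exactly at zero missingness (the keystone property). Missingness is
applied per field afterwards.

Key defaults and their origins:

- **Composition** 174/114/169/590 legacy oligodendroglioma /
  oligoastrocytoma / astrocytoma / glioblastoma + 75 unknown-histology cases
  (the legacy cohort structure being emulated).
- **Truth mixes** per legacy type (e.g. 92% of legacy glioblastomas stay
  IDH-wildtype glioblastoma, 8% become IDH-mutant grade-4 astrocytoma;
  legacy oligoastrocytomas split 35/45/20 across
  oligodendroglioma/astrocytoma/glioblastoma truths) are plausible rates
  chosen once to reproduce the qualitative reclassification flows —
  molecular glioblastomas out of lower-grade histologies, the dissolution of
  the oligoastrocytoma type, rare H3-mutant exits.
- **Missingness** ~5–15% per molecular field, highest for H3 (0.15) and IDH
  (0.10), mirroring that these are the dominant causes of NA diagnoses.
- **Survival**: exponential event times with per-class medians (months)
  140 / 90.5 / 105.1 / 67.4 / 38.7 / 14.0 for oligodendroglioma 2/3,
  astrocytoma 2/3/4 and glioblastoma — the published group medians where
  defined; 140 stands in for the grade-2 oligodendroglioma group whose
  curve never reaches 0.5. Censoring is independent exponential at rate
  λr/(1−r), which censors an expected fraction r (default 0.3) while
  keeping Kaplan–Meier estimates unbiased; r = 1 censors everything.
- **Expression**: log-normal baseline (per-gene log2 mean ~ N(6, 1.5),
  within-class SD 1); class-family marker blocks of 30 genes shifted by 2 SD
  by default; 50-gene subtype signature blocks within the glioblastoma
  class; CRNDE/FREM2/SPRY1, the four risk genes and a nested three-variant
  FREM2-like pathway (activators up, repressors down in glioblastoma).
  18 cases contribute two aliquots with extra within-case noise to emulate
  multi-aliquot profiling.
- **Methylation**: gene-level beta means 0.45 baseline, ±0.35 class shifts
  (IDH-mutant families hyper-, glioblastoma hypo-methylated), 2 probes per
  gene with 0.03 probe noise.

What the generator does **not** emulate: real expression distributions and
their heteroskedasticity, batch effects, probe-level methylation geometry,
correlated missingness across fields, or non-proportional hazards. Passing
tests therefore demonstrate the correctness of the algorithms under known
ground truth, not the reproduction of any real cohort's numbers; quantities
that depend on the actual data (e.g. the exact percent of significant
survival pairs) take cohort-specific values here.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 1122-case composition for
classification and survival, ~480 genes × ~1140 aliquots for expression,
and ~60 consensus iterations for clustering; closed-form checks use n = 5000
survival draws and 100 seeded replicates for Cox CI coverage. PAL agrees
with direct term-by-term evaluation to 1e-12 relative; AUC equals brute
pair counting to 1e-12. K-means ties, linkage ties and label conflicts are
all broken deterministically (seeded generator, lexicographic sample order,
assignment by maximum total score).

## Known limitations

- Only the adult-type diffuse glioma logic plus the two H3 pediatric-type
  exits is implemented; other CNS5 entities are out of scope.
- The survival analysis is univariate by design; no age/sex adjustment.
- The NA taxonomy cannot distinguish sub-causes beyond the four encoded
  reasons.
- Subtype labelling of clusters is algorithmic (mean signature score);
  heatmap-based visual assignment may differ on borderline clusters.
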