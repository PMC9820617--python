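# glioma-cns5

Reclassification of adult diffuse gliomas from legacy histology-only
diagnoses to the 2021 WHO CNS5 molecular taxonomy, with the downstream
analyses such a re-annotation enables: consensus clustering of expression
and DNA methylation, glioblastoma transcriptional subtyping, survival
comparison across diagnosis groups, and pathway/gene biomarker evaluation.
A synthetic-cohort generator with known ground truth makes every stage
testable end-to-end without any data download.

Intended users: computational biologists working with legacy-annotated
glioma cohorts (TCGA-style tables, MAF mutation files, normalized expression
and methylation matrices) who need current molecular diagnoses and the
standard analyses on top of them.

## What it computes

**Rule engine.** Each case's molecular feature vector — IDH1/2 status,
1p/19q codeletion, ATRX, TERT promoter, EGFR amplification, +7/−10,
CDKN2A/B homozygous deletion, histone H3 hotspots — is mapped through a
fixed decision order to a CNS5 diagnosis:

- *oligodendroglioma, IDH-mutant and 1p/19q-codeleted* (grade 2–3),
- *astrocytoma, IDH-mutant* (grade 2–4; grade 4 on CDKN2A/B homozygous
  deletion or grade-IV histology),
- *glioblastoma, IDH-wildtype* (grade 4; called on grade-IV histology or any
  molecular glioblastoma feature),
- the pediatric-type H3 K27-altered / H3 G34-mutant exits,
- or NA with an explicit reason when the defining markers are unresolved.

Every call records its rule trace, and the engine is total: any feature
combination yields exactly one diagnosis.

**Hotspot extraction.** IDH status from MAF files (missense at IDH1 R132 or
IDH2 R172) and H3 status (K27M / G34R in either HGVS numbering convention),
distinguishing confirmed wildtype from absent genomic data.

**Pathway activation level.** PAL_p = Σ ARR_n · log10(CNR_n) · 100 / Σ|ARR_n|,
where CNR is each gene's expression relative to the cohort-average reference
and ARR ∈ {−1, −0.5, 0, 0.5, 1} encodes activator/repressor roles.

**Survival.** Kaplan–Meier medians with log-log CIs, univariate Cox hazard
ratios against a reference group, the all-pairs log-rank matrix with star
coding and a significant-pair-fraction summary, and a median-split
expression risk score.

**Clustering & biomarkers.** Seeded consensus k-means with ARI/NMI agreement
against any labeling, Ward dendrograms, signature-based glioblastoma
subtyping, and rank-statistic ROC AUC for any gene or PAL biomarker between
diagnosis groups.

## Worked example

```python
from glioma_cns5 import SimConfig, classify_cohort, simulate_cohort
from glioma_cns5.survival import survival_groups, km_median, cox_hr

cfg = SimConfig(seed=7)                  # study-scale synthetic cohort
cases, truth = simulate_cohort(cfg)
result = classify_cohort(cases)
print(f"{len(cases)} cases: {result.n_analyzed} analyzed, "
      f"{result.n_updated} definite CNS5 diagnoses, {result.n_na} NA, "
      f"{result.n_excluded} excluded")
print("NA reasons:", dict(result.na_reason_counts()))

groups = survival_groups(cases, result.diagnoses, grouping="cns5")
for label in ("GBM_4", "A_4"):
    sub = groups[groups["group"] == label]
    m = km_median(sub["time"], sub["event"])
    print(f"{label}: median OS {m.median:.1f} months "
          f"(95% CI {m.ci_lower:.1f}-{m.ci_upper:.1f}, n={m.n})")
forest = cox_hr(groups["group"], groups["time"], groups["event"], "GBM_4")
a4 = next(r for r in forest if r.group == "A_4")
print(f"HR A_4 vs GBM_4: {a4.hr:.2f} (95% CI {a4.ci_lower:.2f}-{a4.ci_upper:.2f})")
```

Output:

```
1122 cases: 1047 analyzed, 836 definite CNS5 diagnoses, 211 NA, 75 excluded
NA reasons: {'idh_unknown': 110, 'codel_unresolvable': 15, 'h3_unknown': 85, 'nec': 1}
GBM_4: median OS 15.1 months (95% CI 11.7-17.6, n=470)
A_4: median OS 37.5 months (95% CI 14.2-74.0, n=34)
HR A_4 vs GBM_4: 0.42 (95% CI 0.28-0.63)
```

The 75 unknown-histology cases are excluded up front; of the 1047 analyzed,
most receive a definite molecular diagnosis and the rest land in NA with a
reason (unknown IDH status dominating). The newly separable grade-4
IDH-mutant astrocytomas show a markedly better prognosis than IDH-wildtype
glioblastomas (HR well below 1), while the glioblastoma median OS sits near
its planted 14 months.

The same pipeline is scriptable from the shell:

```
glioma-cns5 simulate --seed 7 --out cohort/
glioma-cns5 classify --cohort cohort/cohort.tsv --out diagnoses.tsv --report rules.tsv
glioma-cns5 survive --cohort cohort/cohort.tsv --grouping cns5 --reference GBM_4 --out surv/
```

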