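"""The WHO CNS5 reclassification rule engine for adult diffuse gliomas.

Decision order (each case fires exactly one terminal rule; the engine is a
total function over all feature combinations):

R0   histology unknown                    -> excluded from analysis
R1   IDH status unknown                   -> NA (idh_unknown)
R2a  IDH-mut, 1p/19q codeleted            -> oligodendroglioma, IDH-mut & codel (grade 2/3)
R2b  IDH-mut, not codeleted — or codel
     unknown with ATRX mutant (the ATRX
     shortcut obviates 1p/19q testing)    -> astrocytoma, IDH-mut (grade 2/3/4;
                                             grade 4 on CDKN2A/B HD or legacy grade IV)
R2c  IDH-mut, codel unknown, ATRX not mut -> NA (codel_unresolvable)
R3a  IDH-wt, H3 K27M                      -> pediatric-type H3 K27-altered diffuse midline glioma
R3b  IDH-wt, H3 G34-mutant                -> pediatric-type H3 G34-mutant diffuse hemispheric glioma
R3c  IDH-wt, H3 unknown                   -> NA (h3_unknown)
R3d  IDH-wt, H3-wt, legacy grade IV or any
     molecular GBM feature (TERTp mut /
     EGFR amp / +7-10)                    -> glioblastoma, IDH-wt, grade 4
R3e  IDH-wt, H3-wt, lower grade, no
     molecular GBM feature                -> NA (nec; "not elsewhere classified")

WHO CNS5 oligodendroglioma has no grade 4, so a codeleted IDH-mutant case
with legacy grade IV is emitted as grade 3 with a warning flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import CaseAnnotation

__all__ = [
    "Cns5Diagnosis",
    "CohortClassification",
    "classify_case",
    "classify_cohort",
    "rule_coverage_report",
    "CATEGORIES",
    "RULES",
    "DEFINITE_CATEGORIES",
]

OLIGO = "OLIGO_IDH_MUT_CODEL"
ASTRO = "ASTRO_IDH_MUT"
GBM = "GBM_IDH_WT"
PED_K27 = "PEDIATRIC_H3_K27"
PED_G34 = "PEDIATRIC_H3_G34"
NA = "NA"
EXCLUDED = "EXCLUDED_UNKNOWN_HISTOLOGY"

CATEGORIES = (OLIGO, ASTRO, GBM, PED_K27, PED_G34, NA, EXCLUDED)
DEFINITE_CATEGORIES = (OLIGO, ASTRO, GBM, PED_K27, PED_G34)

RULES: dict[str, str] = {
    "R0": "histology unknown -> excluded",
    "R1": "IDH status unknown -> NA",
    "R2": "IDH-mutant branch",
    "R2a": "IDH-mut + 1p/19q codeletion -> oligodendroglioma",
    "R2b": "IDH-mut, non-codel (or ATRX-mut shortcut) -> astrocytoma",
    "R2c": "IDH-mut, codeletion unresolvable -> NA",
    "R3": "IDH-wildtype branch",
    "R3a": "IDH-wt + H3 K27M -> pediatric diffuse midline glioma",
    "R3b": "IDH-wt + H3 G34-mut -> pediatric diffuse hemispheric glioma",
    "R3c": "IDH-wt, H3 unknown -> NA",
    "R3d": "IDH-wt, H3-wt + grade IV or molecular GBM feature -> glioblastoma",
    "R3e": "IDH-wt, H3-wt lower grade without GBM features -> NA (NEC)",
}

TERMINAL_RULES = ("R0", "R1", "R2a", "R2b", "R2c", "R3a", "R3b", "R3c", "R3d", "R3e")

NA_REASONS = ("idh_unknown", "h3_unknown", "codel_unresolvable", "nec", "none")


@dataclass(frozen=True)
class Cns5Diagnosis:
    """Updated diagnosis with the rule path that produced it."""

    category: str
    grade: int | None
    rule_trace: tuple[str, ...]
    na_reason: str = "none"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.category in CATEGORIES
        assert self.na_reason in NA_REASONS
        if self.category in (NA, EXCLUDED, PED_K27, PED_G34):
            assert self.grade is None
        elif self.category == OLIGO:
            assert self.grade in (2, 3)
        elif self.category == GBM:
            assert self.grade == 4
        elif self.category == ASTRO:
            assert self.grade in (2, 3, 4)

    @property
    def label(self) -> str:
        if self.grade is None:
            return self.category
        return f"{self.category}_g{self.grade}"


def _lower_grade(c: CaseAnnotation, category: str) -> tuple[int, tuple[str, ...]]:
    """Grade 2/3 from the legacy histological grade, with flags for oddities."""
    if c.hist_grade == "II":
        return 2, ()
    if c.hist_grade == "III":
        return 3, ()
    if c.hist_grade == "IV":
        # CNS5 oligodendroglioma tops out at grade 3
        return 3, ("oligo_grade_capped",) if category == OLIGO else ()
    return 2, ("grade_imputed",)


def classify_case(c: CaseAnnotation) -> Cns5Diagnosis:
    """Map one annotated case to its WHO CNS5 diagnosis (total function)."""
    if c.histology == "unknown":
        return Cns5Diagnosis(EXCLUDED, None, ("R0",))
    if c.idh_status == "unknown":
        return Cns5Diagnosis(NA, None, ("R1",), na_reason="idh_unknown")

    if c.idh_status == "mutant":
        if c.codel_1p19q == "yes":
            grade, flags = _lower_grade(c, OLIGO)
            return Cns5Diagnosis(OLIGO, grade, ("R2", "R2a"), flags=flags)
        if c.codel_1p19q == "no" or c.atrx == "mutant":
            trace = ("R2", "R2b")
            if c.cdkn2ab_hd == "yes" or c.hist_grade == "IV":
                return Cns5Diagnosis(ASTRO, 4, trace)
            grade, flags = _lower_grade(c, ASTRO)
            return Cns5Diagnosis(ASTRO, grade, trace, flags=flags)
        return Cns5Diagnosis(NA, None, ("R2", "R2c"), na_reason="codel_unresolvable")

    # IDH-wildtype branch
    if c.h3_status == "K27M":
        return Cns5Diagnosis(PED_K27, None, ("R3", "R3a"))
    if c.h3_status == "G34_mut":
        return Cns5Diagnosis(PED_G34, None, ("R3", "R3b"))
    if c.h3_status == "unknown":
        return Cns5Diagnosis(NA, None, ("R3", "R3c"), na_reason="h3_unknown")
    if (
        c.hist_grade == "IV"
        or c.tertp == "mutant"
        or c.egfr_amp == "yes"
        or c.gain7_loss10 == "yes"
    ):
        return Cns5Diagnosis(GBM, 4, ("R3", "R3d"))
    return Cns5Diagnosis(NA, None, ("R3", "R3e"), na_reason="nec")


# Legacy label -> expected CNS5 (category, grade) under the documented mapping;
# oligoastrocytoma has no CNS5 counterpart and always counts as changed.
_LEGACY_MAP = {
    ("oligodendroglioma", "II"): (OLIGO, 2),
    ("oligodendroglioma", "III"): (OLIGO, 3),
    ("astrocytoma", "II"): (ASTRO, 2),
    ("astrocytoma", "III"): (ASTRO, 3),
    ("glioblastoma", "IV"): (GBM, 4),
}


def legacy_label(c: CaseAnnotation) -> str:
    return f"{c.histology}_{c.hist_grade}"


@dataclass
class CohortClassification:
    """Per-case diagnoses plus the legacy x CNS5 reclassification cross-table."""

    diagnoses: list[Cns5Diagnosis]
    cases: list[CaseAnnotation]
    table: pd.DataFrame = field(init=False)
    changed: list[bool] = field(init=False)

    def __post_init__(self) -> None:
        legacy = [legacy_label(c) for c in self.cases]
        new = [d.label for d in self.diagnoses]
        keep = [d.category != EXCLUDED for d in self.diagnoses]
        self.table = pd.crosstab(
            pd.Series([l for l, k in zip(legacy, keep) if k], name="legacy"),
            pd.Series([n for n, k in zip(new, keep) if k], name="cns5"),
        )
        self.changed = []
        for c, d in zip(self.cases, self.diagnoses):
            if d.category not in DEFINITE_CATEGORIES:
                self.changed.append(False)
                continue
            expected = _LEGACY_MAP.get((c.histology, c.hist_grade))
            self.changed.append(expected != (d.category, d.grade))

    @property
    def n_excluded(self) -> int:
        return sum(d.category == EXCLUDED for d in self.diagnoses)

    @property
    def n_analyzed(self) -> int:
        return len(self.diagnoses) - self.n_excluded

    @property
    def n_na(self) -> int:
        return sum(d.category == NA for d in self.diagnoses)

    @property
    def n_updated(self) -> int:
        """Cases that received a definite CNS5 diagnosis (the reclassified set)."""
        return sum(d.category in DEFINITE_CATEGORIES for d in self.diagnoses)

    def na_reason_counts(self) -> Counter:
        return Counter(d.na_reason for d in self.diagnoses if d.category == NA)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [c.case_id for c in self.cases],
                "legacy": [legacy_label(c) for c in self.cases],
                "cns5_category": [d.category for d in self.diagnoses],
                "cns5_grade": [d.grade for d in self.diagnoses],
                "cns5_label": [d.label for d in self.diagnoses],
                "na_reason": [d.na_reason for d in self.diagnoses],
                "rule_trace": ["|".join(d.rule_trace) for d in self.diagnoses],
                "flags": ["|".join(d.flags) for d in self.diagnoses],
                "changed": self.changed,
            }
        ).set_index("case_id", drop=False)


def classify_cohort(cases: Sequence[CaseAnnotation]) -> CohortClassification:
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("case_ids must be unique within a cohort")
    return CohortClassification([classify_case(c) for c in cases], list(cases))


def rule_coverage_report(result: CohortClassification) -> pd.DataFrame:
    """Hit counts of terminal rules; counts sum to the number of cases."""
    hits = Counter(d.rule_trace[-1] for d in result.diagnoses)
    return pd.DataFrame(
        {
            "rule": list(TERMINAL_RULES),
            "description": [RULES[r] for r in TERMINAL_RULES],
            "hits": [hits.get(r, 0) for r in TERMINAL_RULES],
        }
    ).set_index("rule")
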