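"""Cohort annotation, expression and methylation containers and their TSV/MTX IO.

The per-case annotation table carries one row per glioma case with the legacy
(histology-only) diagnosis and the molecular features the WHO CNS5 rules
consume: IDH1/2 status, 1p/19q codeletion, ATRX, TERT promoter, EGFR
amplification, combined chr7 gain + chr10 loss, CDKN2A/B homozygous deletion,
and histone H3 hotspot status, plus age and overall survival.

Categorical fields use small closed vocabularies; any unrecognized token in an
input file maps to ``unknown`` with a logged warning rather than failing the
read, because real clinical tables are full of site-specific spellings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CaseAnnotation",
    "ExpressionMatrix",
    "MethylationMatrix",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "read_expression",
    "write_expression",
    "read_expression_mtx",
    "read_methylation",
    "write_methylation",
    "aggregate_methylation",
    "COHORT_COLUMNS",
]


class SchemaError(ValueError):
    """An input table is missing a required column or violates a key constraint."""


HISTOLOGIES = ("astrocytoma", "oligoastrocytoma", "oligodendroglioma", "glioblastoma", "unknown")
GRADES = ("II", "III", "IV", "unknown")
MUT_LEVELS = ("mutant", "wildtype", "unknown")
TRISTATE = ("yes", "no", "unknown")
H3_LEVELS = ("K27M", "G34_mut", "wildtype", "unknown")

# Missing-value tokens accepted anywhere (case-insensitive).
_NA_TOKENS = {"", "na", "nan", "none", "null", "unknown", "n/a"}

# Synonyms seen in public annotation tables, normalised onto the canonical levels.
_SYNONYMS = {
    "mut": "mutant",
    "mutated": "mutant",
    "wt": "wildtype",
    "wild-type": "wildtype",
    "wild type": "wildtype",
    "codel": "yes",
    "non-codel": "no",
    "amplified": "yes",
    "not amplified": "no",
    "true": "yes",
    "false": "no",
    "gbm": "glioblastoma",
    "k27m": "K27M",
    "g34_mut": "G34_mut",
    "g34r": "G34_mut",
    "g34": "G34_mut",
    "2": "II",
    "3": "III",
    "4": "IV",
    "g2": "II",
    "g3": "III",
    "g4": "IV",
}


def _normalise(token: str, levels: tuple[str, ...], column: str) -> str:
    raw = token.strip()
    if raw.lower() in _NA_TOKENS:
        return "unknown"
    if raw in levels:
        return raw
    mapped = _SYNONYMS.get(raw.lower())
    if mapped in levels:
        return mapped
    low = raw.lower()
    for level in levels:
        if level.lower() == low:
            return level
    logger.warning("unmapped level %r in column %s -> unknown", raw, column)
    return "unknown"


@dataclass
class CaseAnnotation:
    """One glioma case: legacy diagnosis, molecular feature vector, survival."""

    case_id: str
    histology: str = "unknown"
    hist_grade: str = "unknown"
    idh_status: str = "unknown"
    codel_1p19q: str = "unknown"
    atrx: str = "unknown"
    tertp: str = "unknown"
    egfr_amp: str = "unknown"
    gain7_loss10: str = "unknown"
    cdkn2ab_hd: str = "unknown"
    h3_status: str = "unknown"
    age_at_diagnosis: float | None = None
    os_time: float | None = None
    os_event: int | None = None


_CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "histology": HISTOLOGIES,
    "hist_grade": GRADES,
    "idh_status": MUT_LEVELS,
    "codel_1p19q": TRISTATE,
    "atrx": MUT_LEVELS,
    "tertp": MUT_LEVELS,
    "egfr_amp": TRISTATE,
    "gain7_loss10": TRISTATE,
    "cdkn2ab_hd": TRISTATE,
    "h3_status": H3_LEVELS,
}

COHORT_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(CaseAnnotation))


def _parse_float(token: str) -> float | None:
    if token.strip().lower() in _NA_TOKENS:
        return None
    return float(token)


def read_cohort(path: str | Path) -> list[CaseAnnotation]:
    """Read a cohort annotation TSV into a list of :class:`CaseAnnotation`.

    Raises :class:`SchemaError` when a required column is absent or a case_id
    is duplicated. Unrecognized categorical tokens become ``unknown`` with a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    if df["case_id"].duplicated().any():
        dup = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
        raise SchemaError(f"duplicate case_id {dup!r} in cohort table")

    cases: list[CaseAnnotation] = []
    for row in df.itertuples(index=False):
        kwargs: dict[str, object] = {"case_id": str(getattr(row, "case_id")).strip()}
        for col, levels in _CATEGORICAL_LEVELS.items():
            kwargs[col] = _normalise(str(getattr(row, col)), levels, col)
        kwargs["age_at_diagnosis"] = _parse_float(str(getattr(row, "age_at_diagnosis")))
        kwargs["os_time"] = _parse_float(str(getattr(row, "os_time")))
        ev = _parse_float(str(getattr(row, "os_event")))
        kwargs["os_event"] = None if ev is None else int(ev)
        case = CaseAnnotation(**kwargs)  # type: ignore[arg-type]
        if case.os_time is not None and case.os_time < 0:
            raise SchemaError(f"negative os_time for case {case.case_id!r}")
        if case.hist_grade == "IV" and case.histology not in ("glioblastoma", "unknown"):
            logger.warning(
                "case %s has legacy grade IV with histology %s (expected glioblastoma)",
                case.case_id, case.histology,
            )
        cases.append(case)
    return cases


def _fmt(v: float | int | None) -> str:
    if v is None:
        return "NA"
    if isinstance(v, int):
        return str(v)
    return format(v, "g")


def write_cohort(cases: Iterable[CaseAnnotation], path: str | Path) -> None:
    """Write cases to the canonical TSV (fixed column order, NA for missing)."""
    rows = []
    for c in cases:
        rows.append(
            [c.case_id] +
            ["NA" if getattr(c, col) == "unknown" else getattr(c, col) for col in _CATEGORICAL_LEVELS] +
            [_fmt(c.age_at_diagnosis), _fmt(c.os_time), _fmt(c.os_event)]
        )
    out = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def cohort_frame(cases: Iterable[CaseAnnotation]) -> pd.DataFrame:
    """Cases as a DataFrame indexed by case_id (convenience for analyses)."""
    df = pd.DataFrame([vars(c) for c in cases])
    return df.set_index("case_id", drop=False)


# ---------------------------------------------------------------------------
# Numeric matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of normalized counts with an aliquot->case mapping.

    Several aliquots (columns) may map to the same case; by default each
    sample is its own case.
    """

    values: pd.DataFrame
    aliquot_to_case: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        if not self.aliquot_to_case:
            self.aliquot_to_case = {s: s for s in self.values.columns}
        missing = set(self.values.columns) - set(self.aliquot_to_case)
        if missing:
            raise ValueError(f"samples without a case mapping: {sorted(missing)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationMatrix:
    """Probe- or gene-level beta matrix; betas in [0, 1] or missing."""

    values: pd.DataFrame
    probe_to_gene: dict[str, str] | None = None
    gene_level: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
        if not ok.all():
            raise ValueError("methylation betas must lie in [0, 1] or be missing")
        if self.gene_level and self.values.index.duplicated().any():
            raise ValueError("gene-level methylation matrix has duplicate genes")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path: str | Path, aliquot_to_case: Mapping[str, str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, dict(aliquot_to_case or {}))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", lineterminator="\n")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    aliquot_to_case: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet with sidecar gene and sample lists."""
    from scipy.io import mmread

    mat = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)  # type: ignore[union-attr]
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionMatrix(df, dict(aliquot_to_case or {}))


def read_methylation(path: str | Path, probe_map_path: str | Path | None = None) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mapping: dict[str, str] | None = None
    if probe_map_path is not None:
        mp = pd.read_csv(probe_map_path, sep="\t", dtype=str)
        if not {"probe", "gene"} <= set(mp.columns):
            raise SchemaError("probe map needs columns 'probe' and 'gene'")
        mapping = dict(zip(mp["probe"], mp["gene"]))
    # without a probe map the rows are taken to be genes already
    return MethylationMatrix(df, mapping, gene_level=mapping is None)


def write_methylation(meth: MethylationMatrix, path: str | Path) -> None:
    meth.values.to_csv(path, sep="\t", lineterminator="\n")


def aggregate_methylation(meth: MethylationMatrix, statistic: str = "mean") -> MethylationMatrix:
    """Collapse probe-level betas to one row per gene.

    Per gene and sample the aggregate is the ``mean`` (default) or ``median``
    of that gene's probe betas, missing probes excluded sample-wise. Probes
    absent from the probe->gene map are dropped (count logged).
    """
    if meth.probe_to_gene is None:
        raise ValueError("probe_to_gene mapping required for aggregation")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    mapped = [p for p in meth.values.index if p in meth.probe_to_gene]
    dropped = len(meth.values.index) - len(mapped)
    if dropped:
        logger.info("dropping %d probes with no gene mapping", dropped)
    if not mapped:
        raise ValueError("no probes could be mapped to genes")
    sub = meth.values.loc[mapped]
    genes = pd.Index([meth.probe_to_gene[p] for p in mapped], name="gene")
    grouped = sub.groupby(genes)
    agg = grouped.mean() if statistic == "mean" else grouped.median()
    return MethylationMatrix(agg, probe_to_gene=None, gene_level=True)
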