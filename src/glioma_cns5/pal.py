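"""Pathway activation level (PAL) scoring.

PAL for pathway *p* in one sample is

    PAL_p = sum_n ARR_n * log10(CNR_n) * 100 / sum_n |ARR_n|

where CNR_n is the case-to-normal ratio of gene *n* (its expression divided
by its level in a reference profile) and ARR_n in {-1, -0.5, 0, 0.5, 1}
encodes the gene product's activator/repressor role in the pathway. Positive
PAL means net activation relative to the reference, one PAL unit per percent
of a decade of expression change under unit weights.

The default reference profile is the gene-by-gene mean over the whole cohort,
so a sample identical to the cohort average scores PAL = 0 for every pathway.
The denominator uses |ARR| so that balanced pathways (equal activator and
repressor weight) remain well defined; the literal signed-sum denominator is
available via ``signed_denominator=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, SchemaError

__all__ = [
    "PathwayDefinition",
    "CnrMatrix",
    "PalValue",
    "compute_cnr",
    "compute_pal",
    "batch_pal",
    "read_pathways",
    "write_pathways",
    "ALLOWED_ARR",
]

ALLOWED_ARR = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set with signed activator/repressor weights."""

    name: str
    members: Mapping[str, float]  # gene symbol -> ARR
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        bad = {g: a for g, a in self.members.items() if a not in ALLOWED_ARR}
        if bad:
            raise ValueError(f"pathway {self.name!r} has ARR values outside {ALLOWED_ARR}: {bad}")
        if all(a == 0 for a in self.members.values()):
            raise ValueError(f"pathway {self.name!r} has no member with nonzero ARR")

    def negated(self) -> "PathwayDefinition":
        return PathwayDefinition(self.name, {g: -a for g, a in self.members.items()}, dict(self.metadata))


@dataclass
class CnrMatrix:
    """Gene x sample case-to-normal ratios plus the reference profile used."""

    values: pd.DataFrame
    reference: pd.Series

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValueError("CNR values must be positive and finite")


def compute_cnr(
    expr: ExpressionMatrix,
    reference: str | pd.Series = "cohort_average",
    pseudocount: float = 1.0,
) -> CnrMatrix:
    """Case-to-normal ratios: (expr + pseudocount) / (reference + pseudocount).

    ``reference`` is either the string ``"cohort_average"`` (gene-by-gene mean
    over all samples of the matrix) or an explicit per-gene profile covering
    every gene.
    """
    if expr.values.empty:
        raise ValueError("expression matrix is empty")
    if isinstance(reference, str):
        if reference != "cohort_average":
            raise ValueError(f"unknown reference mode {reference!r}")
        ref = expr.values.mean(axis=1)
    else:
        missing = set(expr.genes) - set(reference.index)
        if missing:
            raise ValueError(f"reference profile missing genes: {sorted(missing)[:5]}")
        ref = reference.loc[expr.genes].astype(float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and ((ref == 0).any() or (expr.values.to_numpy() == 0).any()):
        raise ValueError(
            "zero expression or reference encountered with pseudocount=0; "
            "use a positive pseudocount"
        )
    cnr = expr.values.add(pseudocount).div(ref + pseudocount, axis=0)
    return CnrMatrix(cnr, ref)


class PalValue(NamedTuple):
    value: float
    coverage: float  # fraction of pathway members found in the CNR matrix
    n_used: int


def _pathway_weights(p: PathwayDefinition, genes: pd.Index, signed_denominator: bool) -> tuple[pd.Series, float]:
    present = [g for g in p.members if g in genes]
    if not present:
        raise ValueError(f"no member of pathway {p.name!r} is present in the CNR matrix")
    arr = pd.Series({g: p.members[g] for g in present}, dtype=float)
    denom = float(arr.sum()) if signed_denominator else float(arr.abs().sum())
    if denom == 0:
        raise ValueError(
            f"pathway {p.name!r}: denominator is zero for the present members"
            + ("" if signed_denominator else " (all present ARR are 0)")
        )
    return arr, denom


def compute_pal(
    p: PathwayDefinition,
    cnr: CnrMatrix,
    sample: str,
    signed_denominator: bool = False,
) -> PalValue:
    """PAL of one pathway in one sample; members absent from the matrix are
    excluded from numerator and denominator and reflected in ``coverage``."""
    arr, denom = _pathway_weights(p, cnr.values.index, signed_denominator)
    logs = np.log10(cnr.values.loc[arr.index, sample].astype(float))
    value = float((arr * logs).sum() * 100.0 / denom)
    return PalValue(value, len(arr) / len(p.members), len(arr))


def batch_pal(
    pathways: Sequence[PathwayDefinition],
    cnr: CnrMatrix,
    signed_denominator: bool = False,
) -> pd.DataFrame:
    """Pathway x sample PAL matrix (vectorised across samples)."""
    logs = np.log10(cnr.values.astype(float))
    rows = {}
    for p in pathways:
        arr, denom = _pathway_weights(p, cnr.values.index, signed_denominator)
        rows[p.name] = logs.loc[arr.index].mul(arr, axis=0).sum(axis=0) * 100.0 / denom
    out = pd.DataFrame(rows).T
    out.index.name = "pathway"
    return out


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Read pathway definitions from TSV (pathway, gene, ARR) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [PathwayDefinition(d["name"], {g: float(a) for g, a in d["members"].items()},
                                  d.get("metadata", {})) for d in data]
    df = pd.read_csv(path, sep="\t")
    for col in ("pathway", "gene", "ARR"):
        if col not in df.columns:
            raise SchemaError(f"pathway table is missing required column {col!r}")
    out = []
    for name, grp in df.groupby("pathway", sort=False):
        if grp["gene"].duplicated().any():
            raise SchemaError(f"pathway {name!r} lists a gene twice")
        out.append(PathwayDefinition(str(name), dict(zip(grp["gene"], grp["ARR"].astype(float)))))
    return out


def write_pathways(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    rows = [(p.name, g, a) for p in pathways for g, a in p.members.items()]
    pd.DataFrame(rows, columns=["pathway", "gene", "ARR"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
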