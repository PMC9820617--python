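"""Glioblastoma transcriptional subtype assignment (Proneural / Classical /
Mesenchymal) from per-subtype signature gene sets.

Samples are restricted to the signature genes, transformed (log2(x+1) then a
per-gene Z-score by default), Ward-clustered, and each cluster is labelled
with the subtype whose signature genes have the highest mean standardized
expression among the cluster's samples.

The literal transform order ``z_then_log`` (Z-score first, then log2) is kept
behind a flag for comparison; because Z-scores are negative for half the
values it shifts by ``min + 1`` before the log, which is documented as a
non-standard salvage of an otherwise undefined transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .cohort import ExpressionMatrix, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeSignature",
    "SubtypeAssignment",
    "preprocess_signature_matrix",
    "assign_subtypes",
    "read_signatures",
    "write_signatures",
]

SUBTYPE_NAMES = ("Proneural", "Classical", "Mesenchymal")


@dataclass(frozen=True)
class SubtypeSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} lists a gene twice")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")


def read_signatures(path: str | Path) -> list[SubtypeSignature]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("subtype", "gene"):
        if col not in df.columns:
            raise SchemaError(f"signature table is missing required column {col!r}")
    sigs = [SubtypeSignature(str(name), tuple(grp["gene"])) for name, grp in df.groupby("subtype", sort=False)]
    union = [g for s in sigs for g in s.genes]
    if len(set(union)) != len(union):
        raise SchemaError("subtype signatures must be disjoint gene lists")
    return sigs


def write_signatures(sigs: Sequence[SubtypeSignature], path: str | Path) -> None:
    rows = [(s.name, g) for s in sigs for g in s.genes]
    pd.DataFrame(rows, columns=["subtype", "gene"]).to_csv(path, sep="\t", index=False, lineterminator="\n")


def preprocess_signature_matrix(
    expr: ExpressionMatrix,
    signatures: Sequence[SubtypeSignature],
    order: str = "log_then_z",
) -> pd.DataFrame:
    """Restrict to signature genes and standardize per gene.

    Returns a gene x sample matrix with per-gene mean 0 and sd 1 (after the
    Z step). Signature genes absent from the matrix and zero-variance genes
    are dropped with a logged list.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("need at least two samples to standardize")
    wanted = [g for s in signatures for g in s.genes]
    present = [g for g in wanted if g in expr.values.index]
    absent = sorted(set(wanted) - set(present))
    if absent:
        logger.info("signature genes absent from matrix (dropped): %s", absent)
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    sub = expr.values.loc[present].astype(float)

    if order == "log_then_z":
        sub = np.log2(sub + 1.0)
    elif order == "z_then_log":
        pass
    else:
        raise ValueError(f"unknown transform order {order!r}")

    sd = sub.std(axis=1, ddof=0)
    constant = sub.index[sd == 0].tolist()
    if constant:
        logger.info("dropping %d zero-variance signature genes", len(constant))
        sub = sub.drop(index=constant)
        sd = sd.drop(index=constant)
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)

    if order == "z_then_log":
        shifted = z - z.min(axis=1).min() + 1.0
        z = np.log2(shifted)
        # re-standardize so downstream scoring is comparable across genes
        z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1, ddof=0), axis=0)
    return z


@dataclass
class SubtypeAssignment:
    labels: pd.Series          # sample -> subtype name
    clusters: pd.Series        # sample -> cluster id (1..k)
    scores: pd.DataFrame       # cluster x subtype mean signature score
    conflict_resolved: bool = False


def assign_subtypes(
    std_matrix: pd.DataFrame,
    signatures: Sequence[SubtypeSignature],
    k: int = 3,
) -> SubtypeAssignment:
    """Ward-cluster samples of a standardized signature matrix and label the
    clusters by their dominant signature.

    Samples are ordered lexicographically before clustering so that distance
    ties resolve deterministically. When two clusters claim the same subtype
    the conflict is resolved by a maximum-score one-to-one assignment
    (logged); surplus clusters keep their argmax label.
    """
    samples = sorted(std_matrix.columns)
    if len(samples) < k:
        raise ValueError(f"need at least k={k} samples, got {len(samples)}")
    mat = std_matrix[samples].T.to_numpy(dtype=float)

    if k == 1:
        clusters = pd.Series(1, index=samples)
    else:
        Z = linkage(mat, method="ward")
        clusters = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=samples)

    # mean standardized expression of each signature within each cluster
    score_rows = {}
    for cid in sorted(clusters.unique()):
        members = clusters.index[clusters == cid]
        score_rows[cid] = {
            s.name: float(std_matrix.loc[std_matrix.index.intersection(s.genes), members].mean().mean())
            for s in signatures
        }
    scores = pd.DataFrame(score_rows).T
    scores.index.name = "cluster"

    argmax = scores.idxmax(axis=1)
    conflict = argmax.duplicated().any()
    if conflict and len(scores) <= len(signatures):
        logger.warning("multiple clusters claim the same subtype; resolving by total-score assignment")
        cost = -scores.to_numpy(dtype=float)
        rows, cols = linear_sum_assignment(cost)
        argmax = pd.Series(
            [scores.columns[c] for c in cols], index=[scores.index[r] for r in rows]
        )
    elif conflict:
        logger.warning("degenerate clustering: %d clusters for %d subtypes; keeping argmax labels",
                       len(scores), len(signatures))

    labels = clusters.map(argmax)
    labels.name = "subtype"
    clusters.name = "cluster"
    return SubtypeAssignment(labels, clusters, scores, conflict_resolved=bool(conflict))
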