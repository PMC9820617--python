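"""Pairwise ROC-AUC evaluation of expression and pathway-activation biomarkers.

The AUC between two diagnosis groups is the rank statistic U / (n1 * n2)
(ties counted half), i.e. the probability that a random sample from the
positive group scores higher than one from the other; significance comes
from the two-sided Mann-Whitney rank-sum test. Orientation is explicit: the
first-listed group of a pair is the positive class, so
AUC(A vs B) = 1 - AUC(B vs A) exactly, including ties.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cohort import ExpressionMatrix
from .survival import stars

logger = logging.getLogger(__name__)

__all__ = ["AucResult", "pairwise_auc", "biomarker_panel", "DEFAULT_USEFULNESS_THRESHOLD"]

# AUC above which a biomarker is flagged as a usable discriminator
DEFAULT_USEFULNESS_THRESHOLD = 0.7


@dataclass(frozen=True)
class AucResult:
    biomarker: str
    positive_group: str
    negative_group: str
    auc: float
    p: float
    n_positive: int
    n_negative: int
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return stars(self.p)


def _auc_pair(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float, bool]:
    if np.ptp(np.r_[pos, neg]) == 0:
        return 0.5, 1.0, True
    res = mannwhitneyu(pos, neg, alternative="two-sided")
    return float(res.statistic) / (len(pos) * len(neg)), float(res.pvalue), False


def pairwise_auc(
    values: pd.Series,
    groups: pd.Series,
    pairs: Sequence[tuple[str, str]] | None = None,
    biomarker: str = "",
) -> list[AucResult]:
    """AUC of one biomarker for every requested (positive, negative) group pair.

    Defaults to all unordered pairs of observed groups, first-listed group
    positive. Pairs need at least two finite values per group. Constant
    values across both groups give AUC 0.5, p 1.0, flagged degenerate.
    """
    values = values.astype(float)
    groups = groups.astype(str)
    common = values.index.intersection(groups.index)
    values, groups = values.loc[common], groups.loc[common]
    finite = np.isfinite(values)
    values, groups = values[finite], groups[finite]
    if pairs is None:
        pairs = list(itertools.combinations(pd.unique(groups), 2))

    out: list[AucResult] = []
    for pos_g, neg_g in pairs:
        pos = values[groups == pos_g].to_numpy()
        neg = values[groups == neg_g].to_numpy()
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError(f"pair ({pos_g}, {neg_g}) needs >= 2 samples per group")
        auc, p, degenerate = _auc_pair(pos, neg)
        out.append(AucResult(biomarker, pos_g, neg_g, auc, p, len(pos), len(neg), degenerate))
    return out


def biomarker_panel(
    expr: ExpressionMatrix,
    grouping: pd.Series,
    genes: Sequence[str] = ("CRNDE", "FREM2", "SPRY1"),
    pal_matrix: pd.DataFrame | None = None,
    usefulness_threshold: float = DEFAULT_USEFULNESS_THRESHOLD,
) -> pd.DataFrame:
    """Long-format AUC table: one row per (biomarker, group pair).

    Biomarkers are single-gene expression rows plus, optionally, rows of a
    pathway x sample PAL matrix. Biomarkers absent from the matrices are
    skipped with a warning. A single-group labelling yields an empty table.
    """
    grouping = grouping.astype(str)
    levels = list(pd.unique(grouping))
    rows: list[AucResult] = []
    if len(levels) >= 2:
        sources: list[tuple[str, pd.Series]] = []
        for gene in genes:
            if gene not in expr.values.index:
                logger.warning("biomarker gene %s absent from expression matrix; skipped", gene)
                continue
            sources.append((gene, expr.values.loc[gene]))
        if pal_matrix is not None:
            for pw in pal_matrix.index:
                sources.append((f"PAL:{pw}", pal_matrix.loc[pw]))
        for name, vals in sources:
            rows.extend(pairwise_auc(vals, grouping, biomarker=name))

    df = pd.DataFrame([vars(r) | {"stars": r.stars} for r in rows],
                      columns=["biomarker", "positive_group", "negative_group",
                               "auc", "p", "n_positive", "n_negative", "degenerate", "stars"])
    if len(df):
        df["useful"] = np.maximum(df["auc"], 1 - df["auc"]) > usefulness_threshold
    else:
        df["useful"] = pd.Series(dtype=bool)
    return df
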