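"""Survival analytics over diagnosis groups.

Kaplan-Meier medians with exponential-Greenwood (log-log) confidence
intervals, univariate Cox hazard ratios against a reference group, the
all-pairs log-rank matrix with star coding (* p<=0.05, ** p<=0.01,
*** p<=0.001), the significant-pair fraction summary, and the median-split
risk-score model. All fitting is delegated to lifelines.

Medians are reported in the time unit of the input (months throughout this
package); a median is NA (NaN here) when the survival curve never reaches
0.5, which routinely happens for long-surviving low-grade glioma groups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from statsmodels.stats.multitest import multipletests

from .cohort import CaseAnnotation, ExpressionMatrix
from . import rules as R

logger = logging.getLogger(__name__)

__all__ = [
    "KmMedian",
    "CoxGroupResult",
    "PairwiseResult",
    "RiskScoreModel",
    "RiskSplitResult",
    "km_median",
    "cox_hr",
    "pairwise_logrank",
    "significant_fraction",
    "risk_split",
    "survival_groups",
    "stars",
    "LEGACY_GROUPS",
    "CNS5_GROUPS",
]

LEGACY_GROUPS = ("O_II", "O_III", "OA_II", "OA_III", "A_II", "A_III", "GBM_IV")
CNS5_GROUPS = ("O_2", "O_3", "A_2", "A_3", "A_4", "GBM_4")

_LEGACY_ABBR = {
    "oligodendroglioma": "O",
    "oligoastrocytoma": "OA",
    "astrocytoma": "A",
    "glioblastoma": "GBM",
}

_CNS5_ABBR = {R.OLIGO: "O", R.ASTRO: "A", R.GBM: "GBM"}


def stars(p: float) -> str:
    """Significance stars at the conventional thresholds."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


class KmMedian(NamedTuple):
    median: float   # NaN when the curve never reaches 0.5
    ci_lower: float
    ci_upper: float
    n: int
    n_events: int


def _nan_if_inf(x: float) -> float:
    return float("nan") if np.isinf(x) else float(x)


def km_median(times: Sequence[float], events: Sequence[int]) -> KmMedian:
    """Kaplan-Meier median overall survival with a 95% log-log CI.

    The median is the first time the product-limit estimate drops to <= 0.5;
    NA (NaN) when it never does, as for heavily censored groups.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one observation")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    med = _nan_if_inf(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = (_nan_if_inf(v) for v in ci.iloc[0].tolist())
    return KmMedian(med, lo, hi, len(t), int(e.sum()))


def km_curve(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """The KM step function (right-continuous, non-increasing, starts at 1)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    sf.columns = ["survival"]
    return sf


@dataclass
class CoxGroupResult:
    group: str
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    n: int
    n_events: int
    unstable: bool = False


def cox_hr(
    groups: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
    reference_group: str,
) -> list[CoxGroupResult]:
    """Univariate Cox PH fit with group indicators against a reference.

    The reference group's HR is identically 1. Groups with zero events are
    reported with an ``unstable`` flag rather than dropped.
    """
    g = pd.Series(list(groups), dtype=str)
    if reference_group not in set(g):
        raise ValueError(f"reference group {reference_group!r} not present")
    levels = [lv for lv in pd.unique(g) if lv != reference_group]
    if not levels:
        raise ValueError("need at least two groups")
    df = pd.DataFrame({"T": np.asarray(times, dtype=float), "E": np.asarray(events, dtype=int)})
    for lv in levels:
        df[f"g_{lv}"] = (g == lv).astype(float).to_numpy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    summ = cph.summary

    out = [CoxGroupResult(reference_group, 1.0, 1.0, 1.0, float("nan"),
                          int((g == reference_group).sum()),
                          int(df.loc[(g == reference_group).to_numpy(), "E"].sum()))]
    for lv in levels:
        row = summ.loc[f"g_{lv}"]
        mask = (g == lv).to_numpy()
        n_ev = int(df.loc[mask, "E"].sum())
        if n_ev == 0:
            logger.warning("group %s has zero events; HR estimate is unstable", lv)
        out.append(
            CoxGroupResult(
                lv,
                float(np.exp(row["coef"])),
                float(np.exp(row["coef lower 95%"])),
                float(np.exp(row["coef upper 95%"])),
                float(row["p"]),
                int(mask.sum()),
                n_ev,
                unstable=n_ev == 0,
            )
        )
    return out


@dataclass
class PairwiseResult:
    """All-pairs survival comparison: log-rank p, pair HR, and stars."""

    groups: tuple[str, ...]
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    hr: pd.DataFrame
    alpha: float
    adjust: str

    @property
    def n_pairs(self) -> int:
        return len(self.groups) * (len(self.groups) - 1) // 2

    def star_matrix(self) -> pd.DataFrame:
        p = self.p_adjusted if self.adjust != "none" else self.p
        return p.map(stars)

    def pair_frame(self) -> pd.DataFrame:
        rows = []
        p = self.p_adjusted if self.adjust != "none" else self.p
        for a, b in itertools.combinations(self.groups, 2):
            rows.append({
                "group_a": a, "group_b": b,
                "p": self.p.loc[a, b], "p_adjusted": self.p_adjusted.loc[a, b],
                "hr_a_vs_b": self.hr.loc[a, b],
                "stars": stars(p.loc[a, b]),
                "significant": bool(p.loc[a, b] <= self.alpha),
            })
        return pd.DataFrame(rows)


def pairwise_logrank(
    groups: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
    alpha: float = 0.05,
    adjust: str = "none",
) -> PairwiseResult:
    """Log-rank p-value and Cox HR for every unordered pair of groups.

    ``adjust='BH'`` applies Benjamini-Hochberg across the pairs; star coding
    and the significance call then use the adjusted values. The HR matrix is
    anti-symmetric under inversion: HR[a, b] = 1 / HR[b, a].
    """
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    g = pd.Series(list(groups), dtype=str)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    levels = tuple(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least two groups")

    p = pd.DataFrame(np.nan, index=levels, columns=levels, dtype=float)
    hr = pd.DataFrame(np.nan, index=levels, columns=levels, dtype=float)
    np.fill_diagonal(hr.values, 1.0)
    for a, b in itertools.combinations(levels, 2):
        ma, mb = (g == a).to_numpy(), (g == b).to_numpy()
        if ma.sum() == 0 or mb.sum() == 0:
            continue
        res = logrank_test(t[ma], t[mb], e[ma], e[mb])
        p.loc[a, b] = p.loc[b, a] = float(res.p_value)
        sub = pd.DataFrame({"T": np.r_[t[ma], t[mb]], "E": np.r_[e[ma], e[mb]],
                            "x": np.r_[np.ones(ma.sum()), np.zeros(mb.sum())]})
        if sub["E"].sum() == 0 or sub["x"].nunique() < 2:
            continue
        try:
            cph = CoxPHFitter()
            cph.fit(sub, duration_col="T", event_col="E")
            h = float(np.exp(cph.summary.loc["x", "coef"]))
            hr.loc[a, b] = h
            hr.loc[b, a] = 1.0 / h
        except Exception:  # zero-event or separated pairs stay NA
            logger.warning("Cox fit failed for pair (%s, %s)", a, b)

    padj = p.copy()
    pairs = list(itertools.combinations(levels, 2))
    raw = np.array([p.loc[a, b] for a, b in pairs])
    ok = ~np.isnan(raw)
    if ok.any():
        adj = np.full_like(raw, np.nan)
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        for (a, b), v in zip(pairs, adj):
            padj.loc[a, b] = padj.loc[b, a] = v
    return PairwiseResult(levels, p, padj, hr, alpha, adjust)


def significant_fraction(result: PairwiseResult, alpha: float = 0.05) -> dict[str, float]:
    """Share of significant pairwise comparisons, percent rounded to integer."""
    pmat = result.p_adjusted if result.adjust != "none" else result.p
    vals = [pmat.loc[a, b] for a, b in itertools.combinations(result.groups, 2)]
    n_pairs = len(vals)
    if n_pairs == 0:
        raise ValueError("no pairs to summarize")
    n_sig = int(sum(1 for v in vals if not np.isnan(v) and v <= alpha))
    return {"n_sig": n_sig, "n_pairs": n_pairs, "percent": round(100.0 * n_sig / n_pairs)}


# ---------------------------------------------------------------------------
# Risk-score model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskScoreModel:
    """Linear expression risk score; splits a cohort at the median score."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"FN1": 1.0, "ITGA5": 1.0, "OSMR": 1.0, "NGFR": 1.0}
    )

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("risk model needs at least one nonzero coefficient")


@dataclass
class RiskSplitResult:
    labels: pd.Series            # sample -> 'high' | 'low'
    scores: pd.Series
    hr_high_vs_low: float
    ci_lower: float
    ci_upper: float
    p: float
    curves: dict[str, pd.DataFrame]


def risk_split(
    model: RiskScoreModel,
    expr: ExpressionMatrix,
    times: Sequence[float],
    events: Sequence[int],
) -> RiskSplitResult:
    """Score = sum coef * expression, split at the median score, Cox HR of
    high vs low. Ties at the median go to the low-risk group."""
    missing = [gene for gene in model.coefficients if gene not in expr.values.index]
    if missing:
        raise ValueError(f"risk-model genes absent from expression matrix: {missing}")
    coef = pd.Series(dict(model.coefficients), dtype=float)
    scores = expr.values.loc[coef.index].mul(coef, axis=0).sum(axis=0)
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical; median split impossible")
    med = float(scores.median())
    labels = pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="risk")

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    df = pd.DataFrame({"T": t, "E": e, "x": (labels == "high").astype(float).to_numpy()})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    row = cph.summary.loc["x"]
    curves = {
        lab: km_curve(t[(labels == lab).to_numpy()], e[(labels == lab).to_numpy()])
        for lab in ("high", "low")
    }
    return RiskSplitResult(
        labels,
        scores,
        float(np.exp(row["coef"])),
        float(np.exp(row["coef lower 95%"])),
        float(np.exp(row["coef upper 95%"])),
        float(row["p"]),
        curves,
    )


# ---------------------------------------------------------------------------
# Group construction
# ---------------------------------------------------------------------------

def survival_groups(
    cases: Sequence[CaseAnnotation],
    diagnoses: Sequence[R.Cns5Diagnosis] | None = None,
    grouping: str = "legacy",
) -> pd.DataFrame:
    """Grade-stratified survival groups with times and events.

    ``legacy`` yields up to 7 groups (O/OA/A at grades II-III plus GBM_IV);
    ``cns5`` yields up to 6 (O_2, O_3, A_2, A_3, A_4, GBM_4 from the rule
    engine's definite diagnoses). Cases without survival data, with unknown
    histology/grade, or (for cns5) without a definite adult-type diagnosis
    are omitted.
    """
    rows = []
    if grouping == "legacy":
        for c in cases:
            if c.os_time is None or c.os_event is None:
                continue
            if c.histology in ("unknown",) or c.hist_grade == "unknown":
                continue
            label = f"{_LEGACY_ABBR[c.histology]}_{c.hist_grade}"
            if label in LEGACY_GROUPS:
                rows.append((c.case_id, label, c.os_time, c.os_event))
    elif grouping == "cns5":
        if diagnoses is None:
            raise ValueError("cns5 grouping requires diagnoses")
        for c, d in zip(cases, diagnoses):
            if c.os_time is None or c.os_event is None:
                continue
            if d.category not in _CNS5_ABBR:
                continue
            label = f"{_CNS5_ABBR[d.category]}_{d.grade}"
            if label in CNS5_GROUPS:
                rows.append((c.case_id, label, c.os_time, c.os_event))
    else:
        raise ValueError("grouping must be 'legacy' or 'cns5'")
    return pd.DataFrame(rows, columns=["case_id", "group", "time", "event"]).set_index("case_id")
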