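"""Unsupervised structure discovery: consensus k-means, Ward dendrograms and
partition-vs-label agreement.

Consensus clustering repeats k-means on random sample subsets; the consensus
matrix entry (i, j) is the fraction of iterations in which samples i and j
were clustered together among the iterations where both were drawn. The
final partition is a hierarchical (average-linkage) cut of 1 - consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "ConsensusResult",
    "AgreementReport",
    "consensus_kmeans",
    "dendrogram_tree",
    "label_agreement",
    "top_variable_rows",
    "aliquot_cluster_report",
]


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame      # sample x sample co-clustering frequency
    assignment: pd.Series        # sample -> cluster id (1..k)
    subsample_fraction: float
    iterations: int
    seed: int
    degenerate: bool = False


def consensus_kmeans(
    data: pd.DataFrame,
    k: int,
    iterations: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means over ``data`` (samples as rows, features as columns).

    Deterministic given ``seed``: the subsample draws and every k-means
    restart derive from one seeded generator. ``degenerate`` is set when the
    final cut yields fewer than k non-empty clusters (e.g. identical rows).
    """
    n = data.shape[0]
    if data.empty:
        raise ValueError("empty matrix")
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n_samples, got k={k}, n={n}")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    m = max(k, int(round(subsample_fraction * n)))

    together = np.zeros((n, n))
    both = np.zeros((n, n))
    for _ in range(iterations):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=k, n_init=2, random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(X[idx])
        sampled = np.zeros(n, dtype=bool)
        sampled[idx] = True
        both += np.outer(sampled, sampled)
        full = np.full(n, -1)
        full[idx] = lab
        same = (full[:, None] == full[None, :]) & sampled[:, None] & sampled[None, :]
        together += same

    with np.errstate(invalid="ignore"):
        cons = np.where(both > 0, together / np.maximum(both, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    cons = (cons + cons.T) / 2.0
    consensus = pd.DataFrame(cons, index=data.index, columns=data.index)

    if n == 2:
        assignment = pd.Series([1, 2], index=data.index)
    else:
        Z = linkage(_condensed(1.0 - cons), method="average")
        assignment = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=data.index)
    degenerate = assignment.nunique() < k
    assignment.name = "cluster"
    return ConsensusResult(k, consensus, assignment, subsample_fraction, iterations, seed, degenerate)


def _condensed(dist: np.ndarray) -> np.ndarray:
    return dist[np.triu_indices(dist.shape[0], 1)]


def dendrogram_tree(data: pd.DataFrame, method: str = "ward") -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of rows; returns the linkage matrix and the
    ordered leaf labels. Merge heights are non-decreasing for Ward/average."""
    if data.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    Z = linkage(X, method=method)
    order = [data.index[i] for i in leaves_list(Z)]
    return Z, order


@dataclass
class AgreementReport:
    ari: float
    nmi: float
    table: pd.DataFrame
    n_excluded: int


def label_agreement(assignment: pd.Series, labels: pd.Series) -> AgreementReport:
    """Adjusted Rand index and NMI between a clustering and reference labels.

    Samples with missing labels are excluded (count reported); the sample
    sets must otherwise coincide.
    """
    common = assignment.index.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("assignment and labels share no samples")
    if len(common) != len(assignment.index) or len(common) != len(labels.index):
        raise ValueError("assignment and labels must cover the same samples")
    lab = labels.loc[common]
    keep = lab.notna() & (lab.astype(str) != "NA")
    n_excluded = int((~keep).sum())
    a = assignment.loc[common][keep].astype(str)
    b = lab[keep].astype(str)
    return AgreementReport(
        ari=float(adjusted_rand_score(b, a)),
        nmi=float(normalized_mutual_info_score(b, a)),
        table=pd.crosstab(a.rename("cluster"), b.rename("label")),
        n_excluded=n_excluded,
    )


def top_variable_rows(matrix: pd.DataFrame, n: int = 2000) -> pd.DataFrame:
    """The n rows with the highest variance (feature pre-filter for clustering)."""
    v = matrix.var(axis=1)
    keep = v.sort_values(ascending=False).index[: min(n, len(v))]
    return matrix.loc[keep]


def expression_clustering_matrix(values: pd.DataFrame, n_top: int = 2000) -> pd.DataFrame:
    """Samples x genes matrix ready for clustering normalized counts:
    log2(x+1) transform, then the top variable genes.

    On the linear scale the Euclidean metric is dominated by a handful of
    highly expressed genes; class structure in expression lives on the log
    scale. Methylation betas are already bounded and are clustered as-is.
    """
    logged = np.log2(values.astype(float) + 1.0)
    return top_variable_rows(logged, n_top).T


def aliquot_cluster_report(assignment: pd.Series, aliquot_to_case: Mapping[str, str]) -> pd.DataFrame:
    """Cases whose aliquots landed in different clusters (intratumoral
    heterogeneity report); empty when every multi-aliquot case is coherent."""
    df = pd.DataFrame({
        "aliquot": assignment.index,
        "case": [aliquot_to_case.get(s, s) for s in assignment.index],
        "cluster": assignment.to_numpy(),
    })
    multi = df.groupby("case").filter(lambda g: len(g) > 1 and g["cluster"].nunique() > 1)
    return multi.sort_values(["case", "aliquot"]).reset_index(drop=True)
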