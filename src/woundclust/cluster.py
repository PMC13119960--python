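"""Iterative greedy correlation-seeded gene clustering.

The procedure partitions a dynamic-range-filtered gene list into clusters of
synchronously expressed genes:

1. Take the first gene of the remaining ordered pool as the reference.
2. Compute the correlation c_i between the reference and every remaining
   gene; all genes with c_i strictly greater than the threshold (default
   0.9), together with the reference, form the next cluster.
3. Remove the cluster's genes from the pool and repeat until it is empty.
4. Keep only clusters of size N strictly greater than a minimum (default 10).
5. Label clusters by biological program (here via a user- or truth-supplied
   annotation table; clusters labelled "none" are treated as chance
   correlations and dropped).

The result depends on gene order; the order of the input matrix (i.e. file
order) is canonical and is preserved through filtering. Every filtered gene
ends up in exactly one cluster, singletons included, so the partition
property is checkable; retention is a separate step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger("woundclust")

__all__ = [
    "GeneCluster",
    "GreedyCorrelationClustering",
    "correlation_with_reference",
    "greedy_cluster",
    "retain_large_clusters",
    "annotate_clusters",
]


@dataclass(frozen=True)
class GeneCluster:
    """One cluster in discovery order: reference gene first.

    ``correlations[i]`` is the Pearson r between ``members[i]`` and the
    reference over all retained samples (so ``correlations[0] == 1``).
    """

    index: int
    reference_gene: str
    members: tuple[str, ...]
    correlations: tuple[float, ...]
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        base = f"cluster_{self.index:02d}"
        return f"{base}_{self.label}" if self.label else base


def _rank_rows(X: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(X, axis=1)


def _zscore_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (population sd); constant rows flagged, set to 0."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, constant


class GreedyCorrelationClustering(TransformerMixin, BaseEstimator):
    """Greedy reference-gene correlation clustering of features (genes).

    sklearn orientation: ``fit(X)`` with X of shape (n_samples, n_genes)
    clusters the columns. ``transform(X)`` returns the mean-cluster matrix:
    for each retained cluster, the per-sample mean of the member genes'
    z-scored expression (z-scoring uses the fit-time per-gene mean and
    population sd), i.e. one coordinate per coordinated biological program.

    Parameters
    ----------
    r_threshold : float, default=0.9
        Strict correlation threshold for cluster admission, in (0, 1].
    min_size : int, default=10
        Clusters must have strictly more than ``min_size`` members to be
        retained (size >= 11 at the default).
    method : {"pearson", "spearman"}, default="pearson"
        Correlation type. Spearman ranks the data once up front.

    Attributes
    ----------
    clusters_ : list of GeneCluster
        All clusters in discovery order, singletons included (a partition
        of the genes).
    retained_clusters_ : list of GeneCluster
        Clusters with size > min_size, discovery order preserved.
    labels_ : ndarray of shape (n_genes,)
        Discovery-order cluster index (1-based) per gene.
    """

    def __init__(
        self,
        r_threshold: float = 0.9,
        min_size: int = 10,
        method: str = "pearson",
    ):
        self.r_threshold = r_threshold
        self.min_size = min_size
        self.method = method

    def fit(self, X, y=None):
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must be in (0, 1]")
        if self.method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")
        columns = getattr(X, "columns", None)
        X = check_array(X, ensure_min_samples=2, estimator=self)
        n_genes = X.shape[1]
        names = (
            np.asarray(columns, dtype=object)
            if columns is not None
            else np.array([f"g{i}" for i in range(n_genes)], dtype=object)
        )
        self.n_features_in_ = n_genes
        if columns is not None:
            self.feature_names_in_ = names

        G = X.T  # genes x samples
        self.mean_ = G.mean(axis=1)
        self.scale_ = G.std(axis=1)
        work = _rank_rows(G) if self.method == "spearman" else G
        Z, constant = _zscore_rows(work)
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene(s) cannot join any "
                "cluster; their correlations are reported as 0",
                stacklevel=2,
            )
        n = Z.shape[1]

        labels = np.zeros(n_genes, dtype=int)
        clusters: list[GeneCluster] = []
        pool = np.arange(n_genes)
        while pool.size:
            ref = pool[0]
            rest = pool[1:]
            if constant[ref]:
                r = np.zeros(rest.size)
            else:
                r = Z[rest] @ Z[ref] / n
                r[constant[rest]] = 0.0
            admit = rest[r > self.r_threshold]
            member_idx = np.concatenate(([ref], admit))
            corr = np.concatenate(([1.0], r[r > self.r_threshold]))
            idx = len(clusters) + 1
            clusters.append(
                GeneCluster(
                    index=idx,
                    reference_gene=str(names[ref]),
                    members=tuple(str(names[i]) for i in member_idx),
                    correlations=tuple(float(c) for c in corr),
                )
            )
            labels[member_idx] = idx
            keep = ~np.isin(pool, member_idx, assume_unique=True)
            pool = pool[keep]

        self.labels_ = labels
        self.clusters_ = clusters
        self.retained_clusters_ = [c for c in clusters if c.size > self.min_size]
        self._name_to_col = {str(g): i for i, g in enumerate(names)}
        logger.info(
            "greedy clustering: %d clusters, %d retained (size > %d)",
            len(clusters),
            len(self.retained_clusters_),
            self.min_size,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "clusters_")
        index = getattr(X, "index", None)
        X = check_array(X)
        scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        B = (X - self.mean_) / scale  # samples x genes, z-scored
        cols = {}
        for cl in self.retained_clusters_:
            m = [self._name_to_col[g] for g in cl.members]
            cols[cl.name] = B[:, m].mean(axis=1)
        return pd.DataFrame(cols, index=index)


def correlation_with_reference(
    matrix: pd.DataFrame,
    reference_gene: str,
    candidate_genes,
    method: str = "pearson",
) -> pd.Series:
    """Correlation of each candidate gene with a reference gene.

    Computed across all samples of the genes x samples ``matrix`` (all
    retained locations and days pooled). A constant candidate cannot join any
    cluster: its correlation is reported as 0 with a warning.  A constant
    reference is an error.
    """
    candidates = list(candidate_genes)
    missing = [g for g in [reference_gene] + candidates if g not in matrix.index]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing}")
    G = matrix.loc[[reference_gene] + candidates].to_numpy(dtype=float)
    if method == "spearman":
        G = _rank_rows(G)
    Z, constant = _zscore_rows(G)
    if constant[0]:
        raise ValueError(f"reference gene {reference_gene!r} is constant")
    r = Z[1:] @ Z[0] / G.shape[1]
    if constant[1:].any():
        warnings.warn(
            "constant candidate gene(s) reported with correlation 0",
            stacklevel=2,
        )
        r[constant[1:]] = 0.0
    return pd.Series(r, index=candidates, name=reference_gene)


def greedy_cluster(
    matrix: pd.DataFrame,
    r_threshold: float = 0.9,
    min_size: int = 10,
    method: str = "pearson",
) -> list[GeneCluster]:
    """Run the greedy procedure on a dG-filtered genes x samples matrix.

    Returns ALL clusters (including singletons) in discovery order; apply
    :func:`retain_large_clusters` for the size rule. Gene (row) order of the
    matrix defines the reference order.
    """
    if matrix.empty:
        return []
    est = GreedyCorrelationClustering(
        r_threshold=r_threshold, min_size=min_size, method=method
    ).fit(matrix.T)
    return est.clusters_


def retain_large_clusters(clusters, min_size: int = 10) -> list[GeneCluster]:
    """Keep clusters with size strictly greater than ``min_size``."""
    return [c for c in clusters if c.size > min_size]


def annotate_clusters(clusters, annotation_table: dict | None) -> list[GeneCluster]:
    """Attach biological-program labels; drop clusters labelled "none".

    ``annotation_table`` maps cluster index -> label. A cluster labelled
    "none" is assumed to be correlated by chance and removed. With an empty
    table every cluster is labelled "unannotated" and kept. Labelling a
    nonexistent cluster index is an error.
    """
    clusters = list(clusters)
    table = dict(annotation_table or {})
    known = {c.index for c in clusters}
    unknown = set(table) - known
    if unknown:
        raise KeyError(f"annotation for nonexistent cluster index(es): {sorted(unknown)}")
    out = []
    for c in clusters:
        label = table.get(c.index, "unannotated")
        if label == "none":
            logger.info("cluster %d labelled 'none'; dropped", c.index)
            continue
        out.append(replace(c, label=label))
    return out
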