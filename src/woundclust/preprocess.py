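"""Dynamic-range gene filtering and paired-sample hygiene.

The per-gene dynamic range dG = max_j g_ij - min_j g_ij (over all samples,
pooling locations and days) is the differential-expression proxy: only genes
with dG strictly greater than a threshold (default 4 log2 units) enter
clustering.  Edge-center biopsy pairs from the same wound are tabulated and
near-duplicate pairs — two biopsies evidently taken from almost the same
site — are detected by Pearson correlation of their full expression vectors
and excluded, both samples, from all downstream analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger("woundclust")

__all__ = [
    "DynamicRangeFilter",
    "compute_gene_stats",
    "filter_differential",
    "pair_edge_center",
    "detect_near_duplicates",
    "drop_excluded_samples",
]


class DynamicRangeFilter(TransformerMixin, BaseEstimator):
    """Select genes whose expression dynamic range exceeds a threshold.

    A feature-selection transformer in sklearn orientation (rows are samples,
    columns are genes).  ``fit`` computes per-gene summary statistics over all
    samples; ``transform`` keeps exactly the genes with
    ``dG = max - min > threshold`` (strict), preserving column order.

    Parameters
    ----------
    threshold : float, default=4.0
        Dynamic-range cutoff in log2 units. Must be >= 0.

    Attributes
    ----------
    dynamic_range_ : ndarray of shape (n_genes,)
        dG per gene.
    support_ : ndarray of bool of shape (n_genes,)
        Mask of retained genes.
    stats_ : pandas.DataFrame
        Per-gene I_max, I_min, dG, M (mean) and S (population sd).
    """

    def __init__(self, threshold: float = 4.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        columns = getattr(X, "columns", None)
        X = check_array(X, ensure_min_samples=2, estimator=self)
        i_max = X.max(axis=0)
        i_min = X.min(axis=0)
        self.n_features_in_ = X.shape[1]
        if columns is not None:
            self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.dynamic_range_ = i_max - i_min
        self.support_ = self.dynamic_range_ > self.threshold
        names = (
            self.feature_names_in_
            if columns is not None
            else np.arange(X.shape[1])
        )
        self.stats_ = pd.DataFrame(
            {
                "I_max": i_max,
                "I_min": i_min,
                "dG": self.dynamic_range_,
                "M": X.mean(axis=0),
                "S": X.std(axis=0),  # population convention (ddof=0)
            },
            index=pd.Index(names, name="gene_id"),
        )
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if hasattr(X, "iloc"):
            return X.iloc[:, self.support_]
        X = check_array(X)
        return X[:, self.support_]


def compute_gene_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene I_max, I_min, dG, M, S over ALL samples of a genes x samples matrix.

    Statistics pool every retained sample (edge, center and baseline alike);
    the standard deviation uses the population convention (divide by n).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute gene statistics")
    sel = DynamicRangeFilter().fit(matrix.T)
    return sel.stats_


def filter_differential(
    matrix: pd.DataFrame, stats: pd.DataFrame | None = None, threshold: float = 4.0
) -> pd.DataFrame:
    """Keep genes with dG strictly greater than ``threshold``, order preserved."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if stats is None:
        stats = compute_gene_stats(matrix)
    keep = stats.loc[matrix.index, "dG"] > threshold
    out = matrix.loc[keep.to_numpy()]
    logger.info(
        "dG filter (> %g): kept %d of %d genes", threshold, len(out), len(matrix)
    )
    return out


def pair_edge_center(meta: pd.DataFrame) -> pd.DataFrame:
    """Pair edge and center samples of the same (wound, day).

    Returns a table with columns wound, day, edge_sample, center_sample,
    unpaired (False for true pairs) and excluded (initialized False).
    Baseline samples are never paired.  A wound with two same-location
    samples on one day is an error.
    """
    rows = []
    wounded = meta[meta["location"].isin(["edge", "center"])]
    for (wound, day), grp in wounded.groupby(["wound", "day"], sort=True):
        by_loc: dict[str, str] = {}
        for r in grp.itertuples():
            if r.location in by_loc:
                raise ValueError(
                    f"wound {wound!r} day {day} has two {r.location!r} samples"
                )
            by_loc[r.location] = r.sample_id
        rows.append(
            {
                "wound": wound,
                "day": day,
                "edge_sample": by_loc.get("edge"),
                "center_sample": by_loc.get("center"),
                "unpaired": len(by_loc) < 2,
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["wound", "day", "edge_sample", "center_sample", "unpaired"]
    )
    pairs = pairs.sort_values(["day", "wound"], kind="stable").reset_index(drop=True)
    pairs["excluded"] = False
    return pairs


def detect_near_duplicates(
    matrix: pd.DataFrame, pairs: pd.DataFrame, r_threshold: float = 0.999
) -> pd.DataFrame:
    """Flag edge-center pairs whose expression vectors are nearly identical.

    A pair is flagged ``excluded`` when the Pearson correlation between its
    two full per-gene expression vectors is >= ``r_threshold``.  Pearson r and
    the root-mean-square difference are recorded for every complete pair.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must be in (0, 1]")
    pairs = pairs.copy()
    pairs["pearson_r"] = np.nan
    pairs["rmsd"] = np.nan
    for i, row in pairs.iterrows():
        if row["unpaired"]:
            continue
        e = matrix[row["edge_sample"]].to_numpy()
        c = matrix[row["center_sample"]].to_numpy()
        r = float(np.corrcoef(e, c)[0, 1])
        pairs.at[i, "pearson_r"] = r
        pairs.at[i, "rmsd"] = float(np.sqrt(np.mean((e - c) ** 2)))
        pairs.at[i, "excluded"] = r >= r_threshold
    n_flag = int(pairs["excluded"].sum())
    logger.info("near-duplicate detection (r >= %g): flagged %d pairs", r_threshold, n_flag)
    return pairs


def drop_excluded_samples(
    matrix: pd.DataFrame, meta: pd.DataFrame, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop both samples of every excluded pair from matrix and metadata."""
    excluded = pairs[pairs["excluded"]]
    drop = set(excluded["edge_sample"]) | set(excluded["center_sample"])
    drop.discard(None)
    matrix = matrix.drop(columns=[s for s in matrix.columns if s in drop])
    meta = meta[~meta["sample_id"].isin(drop)].reset_index(drop=True)
    logger.info("excluded %d samples from %d pairs", len(drop), len(excluded))
    return matrix, meta
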