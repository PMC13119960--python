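"""Cluster dynamics: standardization, mean-cluster series and summaries.

Each gene is z-scored over all retained samples, b_ij = (g_ij - M_i) / S_i
(population sd), so every gene fluctuates around 0 with unit spread and
contributes comparably to its cluster.  The mean cluster value
C_kj = mean over cluster-k genes of b_ij is computed per SAMPLE and then
aggregated to per-(day, location) means and standard deviations, preserving
the replicate dispersion needed for error bars.  On top of the series sit
the paired edge-vs-center scatter views, low-dimensional cluster-plane
healing trajectories, and a contamination flag for bursty tissue clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger("woundclust")

__all__ = [
    "GeneStandardizer",
    "standardize",
    "cluster_mean_series",
    "summarize_by_day",
    "pair_scatter",
    "trajectory",
    "flag_contaminated_samples",
    "count_flagged_pairs",
    "FlagReport",
]


class GeneStandardizer(TransformerMixin, BaseEstimator):
    """Per-gene z-scoring with the population standard deviation.

    sklearn orientation (samples x genes). Unlike ``StandardScaler`` it
    refuses constant genes by name instead of silently passing them through:
    a zero-variance gene cannot be standardized (and cannot occur after the
    dynamic-range filter).
    """

    def fit(self, X, y=None):
        columns = getattr(X, "columns", None)
        arr = check_array(X, ensure_min_samples=2, estimator=self)
        self.n_features_in_ = arr.shape[1]
        if columns is not None:
            self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.mean_ = arr.mean(axis=0)
        self.scale_ = arr.std(axis=0)  # ddof=0
        zero = np.flatnonzero(self.scale_ == 0)
        if zero.size:
            names = (
                [str(self.feature_names_in_[i]) for i in zero]
                if columns is not None
                else list(zero)
            )
            raise ValueError(f"constant gene(s) cannot be standardized: {names}")
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        index = getattr(X, "index", None)
        columns = getattr(X, "columns", None)
        arr = check_array(X)
        out = (arr - self.mean_) / self.scale_
        if columns is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


def standardize(matrix: pd.DataFrame, stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Row-standardize a genes x samples matrix: b_ij = (g_ij - M_i) / S_i.

    If ``stats`` (from :func:`woundclust.preprocess.compute_gene_stats`) is
    given, its M and S columns are used; otherwise they are recomputed.
    Every gene in the result has mean 0 and population sd 1 (to 1e-9).
    """
    if stats is not None:
        m = stats.loc[matrix.index, "M"].to_numpy()
        s = stats.loc[matrix.index, "S"].to_numpy()
        zero = matrix.index[s == 0].tolist()
        if zero:
            raise ValueError(f"constant gene(s) cannot be standardized: {zero}")
        values = (matrix.to_numpy(dtype=float) - m[:, None]) / s[:, None]
        return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    est = GeneStandardizer().fit(matrix.T)
    return est.transform(matrix.T).T


def cluster_mean_series(standardized: pd.DataFrame, cluster) -> pd.Series:
    """Mean cluster value C per sample: average of member b rows.

    ``cluster`` is a :class:`~woundclust.cluster.GeneCluster` or an iterable
    of gene ids. A singleton returns that gene's standardized row.
    """
    members = list(getattr(cluster, "members", cluster))
    if not members:
        raise ValueError("empty cluster")
    missing = [g for g in members if g not in standardized.index]
    if missing:
        raise KeyError(f"cluster member(s) not in matrix: {missing}")
    series = standardized.loc[members].mean(axis=0)
    series.name = getattr(cluster, "name", None)
    return series


def summarize_by_day(values: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-(day, location) replicate mean and population sd of a sample series.

    ``values`` is indexed by sample id (a mean-cluster series or one gene's
    row). The day-0 baseline group is computed once and attached to both the
    edge and the center trajectory (rows carry ``from_baseline=True``), since
    unwounded tissue is the shared start state. Groups with zero samples are
    omitted.
    """
    meta = meta[meta["sample_id"].isin(values.index)]
    rows = []
    for (day, loc), grp in meta.groupby(["day", "location"], sort=True):
        v = values.loc[grp["sample_id"]].to_numpy(dtype=float)
        entry = {
            "day": day,
            "mean": float(v.mean()),
            "sd": float(v.std()),  # population convention
            "n": len(v),
        }
        if loc == "baseline":
            for target in ("edge", "center"):
                rows.append({**entry, "location": target, "from_baseline": True})
        else:
            rows.append({**entry, "location": loc, "from_baseline": False})
    out = pd.DataFrame(
        rows, columns=["day", "location", "mean", "sd", "n", "from_baseline"]
    )
    return out.sort_values(["location", "day"], kind="stable").reset_index(drop=True)


def pair_scatter(
    matrix: pd.DataFrame,
    pair: pd.Series | dict,
    highlight_sets: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Per-gene (edge, center) coordinates for one wound's biopsy pair.

    Returns one row per gene with the edge and center expression on the log2
    scale plus a ``highlight`` column naming the first highlight set the gene
    belongs to (e.g. epithelial genes red, muscle genes blue), empty
    otherwise. Requesting an excluded pair is an error.
    """
    if isinstance(pair, dict):
        pair = pd.Series(pair)
    if bool(pair.get("excluded", False)):
        raise ValueError(
            f"pair {pair.get('wound')!r} day {pair.get('day')} is excluded "
            "as a near-duplicate"
        )
    edge_id, center_id = pair["edge_sample"], pair["center_sample"]
    out = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "edge": matrix[edge_id].to_numpy(dtype=float),
            "center": matrix[center_id].to_numpy(dtype=float),
        }
    )
    out["highlight"] = ""
    for name, genes in (highlight_sets or {}).items():
        mask = out["gene_id"].isin(set(genes)) & (out["highlight"] == "")
        out.loc[mask, "highlight"] = name
    return out


def trajectory(
    series_a: pd.Series,
    series_b: pd.Series,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-location healing path in the (A, B) cluster plane.

    For each location, the time-ordered sequence of per-day mean coordinates
    (mean C_A, mean C_B), starting from the shared day-0 baseline point.
    Columns: location, day, a, b, is_start, is_end — start/end flags mark the
    day-0 and final-day points for marker rendering.
    """
    if set(series_a.index) != set(series_b.index):
        raise ValueError("trajectory series cover different sample sets")
    sum_a = summarize_by_day(series_a, meta)
    sum_b = summarize_by_day(series_b, meta)
    merged = pd.merge(
        sum_a[["day", "location", "mean"]],
        sum_b[["day", "location", "mean"]].copy(),
        on=["day", "location"],
        suffixes=("_a", "_b"),
    ).rename(columns={"mean_a": "a", "mean_b": "b"})
    merged = merged.sort_values(["location", "day"], kind="stable").reset_index(drop=True)
    merged["is_start"] = merged["day"] == merged.groupby("location")["day"].transform("min")
    merged["is_end"] = merged["day"] == merged.groupby("location")["day"].transform("max")
    return merged[["location", "day", "a", "b", "is_start", "is_end"]]


@dataclass
class FlagReport:
    """Samples flagged as contaminated by a bursty tissue cluster."""

    tau: float
    flagged: list[str]
    table: pd.DataFrame  # sample_id, day, location, value, flagged


def flag_contaminated_samples(
    series: pd.Series, meta: pd.DataFrame, tau: float = 1.0
) -> FlagReport:
    """Flag samples whose mean-cluster value exceeds ``tau``.

    Intended for tissue-capture clusters (hair/muscle/lipid): a sample with
    C > tau (standardized units) carries a burst of that tissue program.
    """
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    meta = meta[meta["sample_id"].isin(series.index)]
    table = meta[["sample_id", "day", "location"]].copy()
    table["value"] = series.loc[table["sample_id"]].to_numpy(dtype=float)
    table["flagged"] = table["value"] > tau
    flagged = table.loc[table["flagged"], "sample_id"].tolist()
    logger.info("contamination flagging (tau=%g): %d samples", tau, len(flagged))
    return FlagReport(tau=tau, flagged=flagged, table=table)


def count_flagged_pairs(
    report: FlagReport,
    pairs: pd.DataFrame,
    days: tuple[int, int] = (1, 5),
    location: str = "center",
) -> dict:
    """Count wound pairs in a day window whose sample at ``location`` is flagged.

    The denominator is the number of designed pairs in the window (excluded
    near-duplicate pairs included), matching how heterogeneity is reported
    against the collected design.
    """
    lo, hi = days
    window = pairs[(pairs["day"] >= lo) & (pairs["day"] <= hi) & ~pairs["unpaired"]]
    col = f"{location}_sample"
    flagged_set = set(report.flagged)
    n_flagged = int(window[col].isin(flagged_set).sum())
    n_total = len(window)
    return {
        "days": (lo, hi),
        "location": location,
        "flagged_pairs": n_flagged,
        "total_pairs": n_total,
        "percent": 100.0 * n_flagged / n_total if n_total else float("nan"),
    }
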