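from dataclasses import dataclass, field

import pandas as pd
import pytest

import woundclust as wc
from woundclust.pipeline import truth_annotation_table


@dataclass
class PipelineRun:
    """Everything produced by one default end-to-end run."""

    matrix: pd.DataFrame
    meta: pd.DataFrame
    truth: wc.SyntheticTruth
    pairs: pd.DataFrame
    matrix_retained: pd.DataFrame
    meta_retained: pd.DataFrame
    stats: pd.DataFrame
    filtered: pd.DataFrame
    clusters: list = field(default_factory=list)
    retained: list = field(default_factory=list)
    standardized: pd.DataFrame | None = None

    def labelled(self, label: str):
        return next(c for c in self.retained if c.label == label)

    def series(self, label: str) -> pd.Series:
        return wc.cluster_mean_series(self.standardized, self.labelled(label))


def run_default_pipeline(seed: int) -> PipelineRun:
    matrix, meta, truth = wc.generate_dataset(seed=seed)
    pairs = wc.detect_near_duplicates(matrix, wc.pair_edge_center(meta))
    matrix_r, meta_r = wc.drop_excluded_samples(matrix, meta, pairs)
    stats = wc.compute_gene_stats(matrix_r)
    filtered = wc.filter_differential(matrix_r, stats)
    clusters = wc.greedy_cluster(filtered)
    retained = wc.retain_large_clusters(clusters)
    retained = wc.annotate_clusters(retained, truth_annotation_table(retained, truth))
    standardized = wc.standardize(filtered, stats)
    return PipelineRun(
        matrix=matrix,
        meta=meta,
        truth=truth,
        pairs=pairs,
        matrix_retained=matrix_r,
        meta_retained=meta_r,
        stats=stats,
        filtered=filtered,
        clusters=clusters,
        retained=retained,
        standardized=standardized,
    )


@pytest.fixture(scope="session")
def run42() -> PipelineRun:
    """Default synthetic dataset (seed 42) run through the full pipeline."""
    return run_default_pipeline(42)


@pytest.fixture(scope="session")
def dataset42(run42):
    return run42.matrix, run42.meta, run42.truth
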