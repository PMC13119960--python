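"""End-to-end orchestration: simulate/read -> clean -> cluster -> dynamics.

``run_all`` executes the full analysis with one configuration and writes a
run directory with stage subfolders and a JSON manifest (thresholds, seed,
per-stage counts), so runs are auditable and byte-reproducible for a fixed
seed and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import dynamics as _dynamics
from . import evaluate as _evaluate
from . import io as _io
from . import preprocess as _preprocess
from . import synthetic as _synthetic

logger = logging.getLogger("woundclust")

__all__ = ["RunConfig", "run_all", "truth_annotation_table"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    already_logged: bool = True
    simulate: bool = False
    seed: int = 0
    noise_sd: float = 0.15
    tissue_jitter_sd: float = 0.15
    dg_threshold: float = 4.0
    correlation_threshold: float = 0.9
    min_size: int = 10
    dup_r: float = 0.999
    tau: float = 1.0
    locations: tuple[str, ...] | None = None  # optional restriction for clustering
    trajectory_pair: tuple[str, str] = ("epithelial", "immune")
    write_figures: bool = False
    extra_synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.dg_threshold < 0:
            raise ValueError("dg_threshold must be >= 0")
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must be in (0, 1]")
        if not (0 < self.dup_r <= 1):
            raise ValueError("dup_r must be in (0, 1]")
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if not self.simulate and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("need matrix_path and metadata_path unless simulate=True")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("locations", "trajectory_pair"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg


def truth_annotation_table(clusters, truth) -> dict[int, str]:
    """Label each cluster by the majority planted archetype of its members.

    Stands in for GO-based annotation when ground truth is available; a
    cluster whose members are majority-background is labelled "none" (and
    hence dropped by :func:`woundclust.cluster.annotate_clusters`).
    """
    table: dict[int, str] = {}
    for cl in clusters:
        archs = pd.Series(
            [truth.gene_archetype.get(g, "background") for g in cl.members]
        )
        top = archs.mode().iloc[0]
        table[cl.index] = "none" if top == "background" else str(top)
    return table


def run_all(config: RunConfig, out_dir) -> dict:
    """Run every stage, write artifacts under ``out_dir``, return the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(config).items()}, "stages": {}}

    # --- input ---------------------------------------------------------
    truth = None
    if config.simulate:
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        matrix, meta, truth = _synthetic.generate_dataset(
            noise_sd=config.noise_sd,
            tissue_jitter_sd=config.tissue_jitter_sd,
            seed=config.seed,
            **config.extra_synthetic,
        )
        _io.write_matrix(matrix, sim_dir / "matrix.tsv")
        _io.write_metadata(meta, sim_dir / "metadata.tsv")
        truth.to_json(sim_dir / "truth.json")
    else:
        matrix = _io.read_matrix(config.matrix_path, already_logged=config.already_logged)
        meta = _io.read_metadata(config.metadata_path)
    matrix, meta = _io.align_matrix_metadata(matrix, meta)
    manifest["stages"]["input"] = {
        "n_genes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
    }

    # --- duplicate exclusion (before any statistics) -------------------
    pre_dir = out / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    pairs = _preprocess.pair_edge_center(meta)
    pairs = _preprocess.detect_near_duplicates(matrix, pairs, r_threshold=config.dup_r)
    matrix, meta = _preprocess.drop_excluded_samples(matrix, meta, pairs)
    pairs.to_csv(pre_dir / "pairs.tsv", sep="\t", index=False)
    manifest["stages"]["duplicates"] = {
        "n_pairs": int((~pairs["unpaired"]).sum()),
        "n_excluded_pairs": int(pairs["excluded"].sum()),
        "n_samples_retained": int(matrix.shape[1]),
    }

    # --- dG filter -----------------------------------------------------
    stats = _preprocess.compute_gene_stats(matrix)
    stats.to_csv(pre_dir / "gene_stats.tsv", sep="\t", float_format="%.6f")
    filtered = _preprocess.filter_differential(matrix, stats, config.dg_threshold)
    _io.write_matrix(filtered, pre_dir / "filtered_matrix.tsv")
    manifest["stages"]["dg_filter"] = {
        "threshold": config.dg_threshold,
        "n_genes_in": int(matrix.shape[0]),
        "n_genes_kept": int(filtered.shape[0]),
    }

    # --- clustering ----------------------------------------------------
    cl_dir = out / "clusters"
    cl_dir.mkdir(exist_ok=True)
    cluster_input = filtered
    if config.locations:
        keep_ids = meta.loc[meta["location"].isin(config.locations), "sample_id"]
        cluster_input = filtered[keep_ids.tolist()]
    clusters = _cluster.greedy_cluster(
        cluster_input,
        r_threshold=config.correlation_threshold,
        min_size=config.min_size,
    )
    retained = _cluster.retain_large_clusters(clusters, config.min_size)
    if truth is not None:
        retained = _cluster.annotate_clusters(
            retained, truth_annotation_table(retained, truth)
        )
    if retained:
        _io.write_gene_lists(retained, cl_dir)
    summary = pd.DataFrame(
        [
            {
                "index": c.index,
                "reference_gene": c.reference_gene,
                "size": c.size,
                "label": c.label or "",
            }
            for c in retained
        ],
        columns=["index", "reference_gene", "size", "label"],
    )
    summary.to_csv(cl_dir / "cluster_summary.tsv", sep="\t", index=False)
    manifest["stages"]["clustering"] = {
        "r_threshold": config.correlation_threshold,
        "min_size": config.min_size,
        "n_clusters_total": len(clusters),
        "n_clusters_retained": len(retained),
    }

    # --- dynamics ------------------------------------------------------
    dyn_dir = out / "dynamics"
    dyn_dir.mkdir(exist_ok=True)
    standardized = _dynamics.standardize(filtered, stats)
    series = {c.name: _dynamics.cluster_mean_series(standardized, c) for c in retained}
    long_rows = []
    summaries = []
    meta_idx = meta.set_index("sample_id")
    for name, s in series.items():
        for sid, val in s.items():
            long_rows.append(
                {
                    "cluster": name,
                    "sample_id": sid,
                    "day": int(meta_idx.loc[sid, "day"]),
                    "location": meta_idx.loc[sid, "location"],
                    "value": val,
                }
            )
        day_summary = _dynamics.summarize_by_day(s, meta)
        day_summary.insert(0, "cluster", name)
        summaries.append(day_summary)
    pd.DataFrame(
        long_rows, columns=["cluster", "sample_id", "day", "location", "value"]
    ).to_csv(dyn_dir / "cluster_series.tsv", sep="\t", index=False, float_format="%.6f")
    if summaries:
        pd.concat(summaries).to_csv(
            dyn_dir / "day_summaries.tsv", sep="\t", index=False, float_format="%.6f"
        )

    def find_series(label: str):
        matches = [s for n, s in series.items() if label in n]
        return matches[0] if matches else None

    traj_df = None
    s_a = find_series(config.trajectory_pair[0])
    s_b = find_series(config.trajectory_pair[1])
    if s_a is not None and s_b is not None:
        traj_df = _dynamics.trajectory(s_a, s_b, meta)
        traj_df.to_csv(dyn_dir / "trajectory.tsv", sep="\t", index=False, float_format="%.6f")

    flags = {}
    for tissue in ("hair", "muscle", "lipid"):
        s = find_series(tissue)
        if s is None:
            continue
        rep = _dynamics.flag_contaminated_samples(s, meta, tau=config.tau)
        rep.table.to_csv(
            dyn_dir / f"flags_{tissue}.tsv", sep="\t", index=False, float_format="%.4f"
        )
        entry = {"n_flagged_samples": len(rep.flagged)}
        if tissue == "muscle":
            entry["day1_5_center"] = _dynamics.count_flagged_pairs(
                rep, pairs, days=(1, 5), location="center"
            )
        flags[tissue] = entry
    manifest["stages"]["dynamics"] = {
        "n_series": len(series),
        "trajectory": list(config.trajectory_pair) if traj_df is not None else None,
        "contamination": flags,
    }

    if config.write_figures:
        from . import plots as _plots

        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for name, s in series.items():
            _plots.plot_cluster_series(
                _dynamics.summarize_by_day(s, meta), title=name,
                path=fig_dir / f"series_{name}.png",
            )
        if traj_df is not None:
            _plots.plot_trajectory(
                traj_df, labels=config.trajectory_pair, path=fig_dir / "trajectory.png"
            )

    # --- recovery (synthetic runs only) --------------------------------
    if truth is not None:
        ev_dir = out / "evaluate"
        ev_dir.mkdir(exist_ok=True)
        report = _evaluate.cluster_recovery(retained, truth)
        report.confusion.to_csv(ev_dir / "confusion.tsv", sep="\t", index=False)
        with open(ev_dir / "recovery.json", "w") as fh:
            json.dump(
                {
                    "ari": report.ari,
                    "best_jaccard": report.best_jaccard,
                    "n_genes_scored": report.n_genes_scored,
                },
                fh,
                indent=1,
            )
        manifest["stages"]["recovery"] = {"ari": report.ari}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("run complete: %s", out)
    return manifest
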