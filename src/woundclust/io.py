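"""Reading and writing the pipeline's text artifacts.

All on-disk formats are tab-separated text with headers: the expression
matrix (genes x samples, first column ``gene_id``), the sample metadata
table, per-cluster gene lists (one symbol per line, the plain format
geneontology.org accepts), and tidy per-cluster series tables.  Gene order
on disk is authoritative: it defines the reference-gene order of the greedy
clustering, so readers preserve row order exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("woundclust")

VALID_LOCATIONS = {"edge", "center", "baseline"}

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "write_gene_lists",
    "read_gene_list",
    "align_matrix_metadata",
    "load_config",
]


def _check_unique(values, kind: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate {kind} id(s): {sorted(set(dup))}")


def read_matrix(path, already_logged: bool = True) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    With ``already_logged=False`` raw non-negative values are transformed to
    log2(1 + x); otherwise values are taken as-is. Row and column order are
    preserved exactly as read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    try:
        values = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"missing value in gene {gene!r}")
    if not already_logged:
        neg = values.lt(0)
        if neg.any().any():
            gene = values.index[neg.any(axis=1)][0]
            sample = values.columns[neg.loc[gene]][0]
            raise ValueError(
                f"negative raw value at gene {gene!r}, sample {sample!r}"
            )
        values = np.log2(1.0 + values)
    values.index.name = "gene_id"
    logger.info("read matrix %s: %d genes x %d samples", path, *values.shape)
    return values


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV with 4 decimal places."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.4f")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, pig, wound, day, location)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pig": str, "wound": str})
    required = {"sample_id", "pig", "wound", "day", "location"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    _check_unique(meta["sample_id"], "sample")
    bad_loc = set(meta["location"]) - VALID_LOCATIONS
    if bad_loc:
        raise ValueError(f"unknown location value(s): {sorted(bad_loc)}")
    meta["day"] = meta["day"].astype(int)
    if (meta["day"] < 0).any():
        raise ValueError("negative day in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_gene_lists(clusters, directory) -> dict[str, Path]:
    """Write one plain-text gene list per cluster plus an index file.

    Each file has one gene symbol per line — the upload format accepted by
    geneontology.org's enrichment form. Returns {cluster name -> file path}.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index: dict[str, Path] = {}
    for cl in clusters:
        name = getattr(cl, "name", None) or f"cluster_{cl.index}"
        for gene in cl.members:
            if any(ch.isspace() for ch in gene):
                raise ValueError(
                    f"gene name {gene!r} in {name} contains whitespace; "
                    "one-symbol-per-line format would be ambiguous"
                )
        path = directory / f"{name}.txt"
        path.write_text("\n".join(cl.members) + "\n")
        index[name] = path
    with open(directory / "INDEX.tsv", "w") as fh:
        fh.write("cluster\tfile\n")
        for name, path in index.items():
            fh.write(f"{name}\t{path.name}\n")
    logger.info("wrote %d gene lists to %s", len(index), directory)
    return index


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def align_matrix_metadata(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and align a matrix with its metadata.

    Errors if the sample id sets differ (listing the symmetric difference);
    otherwise reorders both to a canonical (day, location, wound) order.
    """
    m_ids, s_ids = set(matrix.columns), set(meta["sample_id"])
    if m_ids != s_ids:
        only_m = sorted(m_ids - s_ids)
        only_s = sorted(s_ids - m_ids)
        raise ValueError(
            f"sample id mismatch: only in matrix {only_m}, only in metadata {only_s}"
        )
    meta = meta.sort_values(
        ["day", "location", "wound", "sample_id"], kind="stable"
    ).reset_index(drop=True)
    matrix = matrix.loc[:, meta["sample_id"].tolist()]
    return matrix, meta


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
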