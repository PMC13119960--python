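"""Cluster-recovery metrics and marker-set overlap.

Recovery compares found clusters against a planted ground truth with the
adjusted Rand index (restricted to planted non-background genes), per-planted
best Jaccard, and a confusion listing.  Marker overlap compares found
clusters against user-supplied gene signatures (e.g. scRNA-seq / ST-seq cell
population markers) via intersection counts, Jaccard, and a hypergeometric
upper-tail probability; all three are descriptive, with no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

__all__ = ["RecoveryReport", "cluster_recovery", "marker_overlap"]


@dataclass
class RecoveryReport:
    ari: float
    #: planted archetype -> best Jaccard with any found cluster
    best_jaccard: dict[str, float]
    #: planted archetype x found cluster gene counts (singletons/background included)
    confusion: pd.DataFrame
    n_genes_scored: int


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def cluster_recovery(found_clusters, truth) -> RecoveryReport:
    """Score found clusters against planted membership.

    The ARI is computed over genes that are planted non-background AND appear
    in one of the given clusters; background genes and genes absent from the
    found clusters are excluded from the ARI but shown in the confusion
    listing. Disjoint gene universes are an error.
    """
    found_clusters = list(found_clusters)
    gene_to_found: dict[str, str] = {}
    for cl in found_clusters:
        for g in cl.members:
            gene_to_found[g] = cl.name
    truth_genes = set(truth.gene_archetype)
    if truth_genes.isdisjoint(gene_to_found) and gene_to_found:
        raise ValueError("found clusters and truth share no genes")

    scored = [
        g
        for g in gene_to_found
        if truth.gene_archetype.get(g, "background") != "background"
    ]
    ari = (
        adjusted_rand_score(
            [truth.gene_archetype[g] for g in scored],
            [gene_to_found[g] for g in scored],
        )
        if scored
        else float("nan")
    )

    archetypes = sorted({a for a in truth.gene_archetype.values()})
    best_jaccard = {}
    for arch in archetypes:
        if arch == "background":
            continue
        planted = set(truth.members(arch))
        best_jaccard[arch] = max(
            (_jaccard(planted, set(cl.members)) for cl in found_clusters),
            default=0.0,
        )

    rows = []
    for arch in archetypes:
        planted = set(truth.members(arch))
        counts = {"unassigned": 0}
        for g in planted:
            counts[gene_to_found.get(g, "unassigned")] = (
                counts.get(gene_to_found.get(g, "unassigned"), 0) + 1
            )
        for name, n in sorted(counts.items()):
            if n:
                rows.append({"archetype": arch, "found_cluster": name, "n_genes": n})
    confusion = pd.DataFrame(rows, columns=["archetype", "found_cluster", "n_genes"])
    return RecoveryReport(
        ari=float(ari),
        best_jaccard=best_jaccard,
        confusion=confusion,
        n_genes_scored=len(scored),
    )


def marker_overlap(clusters, marker_sets: dict, universe_size: int) -> pd.DataFrame:
    """Overlap of each found cluster with each named marker gene set.

    For a cluster of size n and marker set of size K drawn from a universe of
    ``universe_size`` genes, the reported probability is the hypergeometric
    upper tail P(X >= observed intersection).
    """
    clusters = list(clusters)
    for name, genes in marker_sets.items():
        if universe_size < len(set(genes)):
            raise ValueError(f"universe smaller than marker set {name!r}")
    for cl in clusters:
        if universe_size < cl.size:
            raise ValueError(f"universe smaller than cluster {cl.name!r}")
    rows = []
    for cl in clusters:
        cset = set(cl.members)
        for name, genes in marker_sets.items():
            mset = set(genes)
            k = len(cset & mset)
            # P(X >= k) for X ~ Hypergeom(M=universe, n=|marker|, N=|cluster|)
            p = float(hypergeom.sf(k - 1, universe_size, len(mset), len(cset)))
            rows.append(
                {
                    "cluster": cl.name,
                    "marker_set": name,
                    "cluster_size": len(cset),
                    "marker_size": len(mset),
                    "intersection": k,
                    "jaccard": _jaccard(cset, mset),
                    "p_hypergeom": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "marker_set",
            "cluster_size",
            "marker_size",
            "intersection",
            "jaccard",
            "p_hypergeom",
        ],
    )
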