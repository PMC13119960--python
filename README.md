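# woundclust

Correlation-cluster dynamics for spatiotemporal wound-healing transcriptomics.

Acute wound healing is driven by a handful of coordinated gene programs —
immune activation, extracellular-matrix (ECM) remodeling, re-epithelialization,
proliferation — that rise and fall on different schedules and differ between
the wound edge and the wound center. `woundclust` is a small, fully tested
pipeline for bulk expression time courses sampled from both wound regions
(the motivating design: porcine excisional wounds, 150 biopsies over 15 time
points spanning days 0–21, edge and center of each wound plus unwounded day-0
baseline tissue). It is aimed at analysts who have a genes × samples
expression table and per-sample (pig, wound, day, location) metadata and want
interpretable, low-dimensional program dynamics rather than a black-box
embedding.

## Method

All expression values live on the log2 scale, `g_ij = log2(1 + expression)`
for gene *i* in sample *j*. The pipeline is:

1. **Paired-sample hygiene.** Edge and center biopsies of the same wound are
   paired; a pair whose two expression vectors have Pearson r ≥ 0.999 was
   evidently sampled from nearly the same site, and both of its samples are
   excluded from all further analysis.
2. **Dynamic-range filter.** For each gene,
   `dG_i = max_j g_ij − min_j g_ij` over *all* retained samples (locations
   and days pooled); only genes with `dG_i > 4` are kept (strict).
3. **Greedy correlation clustering.** The first gene of the remaining ordered
   list is the reference of cluster *n*; every remaining gene with Pearson
   correlation `c_i > 0.9` to the reference joins cluster *n*; the cluster's
   genes are removed and the step repeats until the list is empty. Clusters
   with `N_n > 10` genes are retained and labelled by biological program
   (annotation hook; gene lists are exported one-symbol-per-line, ready for
   GO enrichment upload).
4. **Mean-cluster dynamics.** Each gene is standardized,
   `b_ij = (g_ij − M_i) / S_i` with `M_i`, `S_i` its mean and (population)
   standard deviation over retained samples, and each cluster is summarized
   by its mean cluster value `C_kj = mean_{i∈cluster k} b_ij` per sample —
   one dynamic variable per program. On top of this sit per-(day, location)
   mean ± sd summaries, edge-vs-center paired scatters, bursty
   tissue-contamination flagging (`C > τ`, default τ = 1), and
   cluster-plane healing trajectories (e.g. the epithelial–immune plane, in
   which healing traces a "round trip" leaving and approximately returning
   to the healthy baseline state).

A seeded synthetic-data generator reproduces the full study design — planted
co-expressed archetypes with realistic temporal/spatial profiles, bursty
hair/muscle/lipid tissue-capture contamination (muscle in exactly 6 of the 30
day 1–5 center biopsies), and two near-duplicate day-3 edge–center pairs —
with complete ground truth, so every stage is testable without downloading
anything. Recovery is scored with the adjusted Rand index and per-program
Jaccard; marker-set overlap (intersection, Jaccard, hypergeometric tail) is
available for comparison against external scRNA-seq/ST-seq signatures.

The core stages are sklearn-style estimators (`DynamicRangeFilter`,
`GeneStandardizer`, `GreedyCorrelationClustering` with
`fit`/`transform`/`get_params`) and compose with sklearn pipelines; the
module-level functions are thin wrappers over them.

## Worked example

```bash
woundclust run-all --simulate --seed 42 --out runs/demo
```

prints

```
150 samples in; 146 retained after duplicate exclusion; 8 clusters retained
```

i.e. the generator produced the full 150-sample design, the two planted
near-duplicate day-3 pairs were detected and removed (150 − 2×2 = 146), and
the greedy procedure recovered one retained cluster per planted program. The
run directory contains, per stage, the pair table, gene statistics, filtered
matrix, per-cluster gene lists and summary:

```
index  reference_gene  size  label
1      IMM0001         30    immune
2      ECM0001         30    ecm
...
```

plus mean-cluster series, per-day summaries, the epithelial–immune
trajectory, contamination flag tables, and `manifest.json`, which for this
run reports a recovery ARI of 1.0 against the planted membership and the
muscle-contamination count over day 1–5 center pairs:

```
{'flagged_pairs': 6, 'total_pairs': 30, 'percent': 20.0}
```

— six of the thirty early center biopsies carry the muscle program, i.e.
20% of center samples captured underlying muscle tissue; their bursty,
non-temporal profile is why tissue-associated clusters must not be read as
healing dynamics.

The same stages are available as `woundclust simulate / preprocess /
cluster / dynamics / evaluate` subcommands and as plain library calls; see
`docs/methods.md` for the model, parameter meanings and design choices.

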