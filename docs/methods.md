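# Methods

## Data model

The pipeline operates on a genes × samples matrix of `g_ij = log2(1 +
expression)` values with per-sample metadata (pig, wound, day, location ∈
{edge, center, baseline}). Day-0 samples are unwounded baseline tissue and
carry the `baseline` location — they belong to neither wound region, and
per-location summaries attach the day-0 group to both the edge and the
center trajectory as a shared start point. The matrix's row (gene) order is
authoritative: the greedy clustering's "first remaining gene" rule makes the
result order-dependent, and file order is the only reproducible choice, so
readers preserve it exactly and it is carried unchanged through filtering.

## Pipeline stages and their parameters

Order of operations: near-duplicate exclusion → dynamic-range filter →
greedy clustering → size retention → annotation → standardization →
series/summaries/trajectories/flags. Duplicate exclusion comes first
because a duplicated sample pair would otherwise inflate every gene-gene
correlation and bias `dG`.

**Near-duplicate exclusion** (`dup_r`, default 0.999). An edge–center pair
whose full expression vectors correlate at r ≥ `dup_r` is treated as two
biopsies of nearly the same site; both samples are dropped. The default is
deliberately extreme: across a genes-axis correlation most same-wound pairs
score 0.6–0.95, but as healing completes, edge and center converge
biologically, and genuinely distinct late-day pairs reach r ≈ 0.994–0.997.
A planted/true co-located pair (copy noise ~0.05 log2 units) scores
≥ 0.9995, so 0.999 sits in a stable gap between "converged but distinct"
and "same site". The threshold is exposed; on datasets with stronger
replicate noise a looser value (e.g. 0.99) may be appropriate.

**Dynamic-range filter** (`dg_threshold`, default 4 log2 units, strict
`>`). Computed over all retained samples pooled — not per time point — so a
gene qualifies by its overall range. The default suits matrices on a 0–20
log2 scale; it is a per-dataset choice.

**Greedy correlation clustering** (`r_threshold` 0.9 strict, `min_size` 10
strict, Pearson by default with Spearman behind a flag). Correlations pool
all retained samples across locations and days (a `locations` restriction
is available); the same clusters are then traced separately in edge and
center, which is what makes edge/center comparison of one program
meaningful. Every filtered gene lands in exactly one cluster — singletons
are materialized, and retention (`N > 10`) is a separate step — so the
partition invariant is checkable. Constant genes cannot survive the dG
filter, but constant candidates are handled defensively (correlation
reported as 0 with a warning). Annotation is a hook: labels come from the
user (in practice, GO enrichment of the exported gene lists) or from
synthetic ground truth; a cluster labelled "none" is treated as correlated
by chance and dropped.

**Standardization and mean cluster value.** Per-gene z-scores use the
population standard deviation (divide by n). This convention makes the
invariants exact — standardized rows have mean 0 and sd 1 to 1e-9, and
standardizing twice is a no-op — and is applied consistently in the per-day
replicate sd summaries. The mean cluster value `C` is computed per sample
and only then aggregated per (day, location), preserving replicate
dispersion for error bars.

**Contamination flagging** (`tau`, default 1.0 standardized units). A
sample with mean-cluster value `C > tau` on a tissue-capture cluster
(hair/muscle/lipid) is flagged. Planted bursts are ≥ 5 log2 units ≈ 4–5
standardized units against ~0.2-unit background fluctuation, so the flag is
insensitive to `tau` over a wide range. The reported "fraction of
contaminated pairs" uses the designed number of pairs in the day window as
denominator (excluded near-duplicate pairs included), i.e. contamination is
reported against the collected design: 6 of 30 day 1–5 center pairs = 20%.

**Trajectories.** For two cluster series, the per-location healing path is
the time-ordered sequence of per-day mean coordinates, prepended with the
shared day-0 baseline point; start (day 0) and end (final day) points are
flagged for marker rendering. Both the per-day path and the per-sample
values are exported. No smoothing or interpolation is applied anywhere —
summaries are raw replicate means.

## Synthetic data generator

`generate_dataset` emulates the motivating study design: 6 baseline day-0
samples; edge and center × 6 replicates on days 1–7, 9, 11, 13; × 3
replicates on days 15, 16, 19, 21 (150 samples, 72 edge + 72 center, 15
days). Per gene,

    g_ij = baseline_i + A_i · γ_{a(i),j} · f_{a(i)}(day_j, loc_j) + ε_ij,

clipped to [0, 20], with ε ~ N(0, `noise_sd`), amplitude `A_i` uniform in
the archetype's amplitude range (default [5, 8], lower bound 5 so every
planted gene clears dG > 4 with margin), and γ a per-(sample, archetype)
multiplicative tissue-composition factor, `max(0, N(1, tissue_jitter_sd))`,
shared by all genes of a program — biopsies capture variable fractions of
each tissue program, which is exactly the heterogeneity that motivates the
tissue-associated-cluster analysis.

Latent profiles `f` (unitless, ~[−1, 1]; baseline location = healthy
tissue: epithelial 1, all else 0):

- **immune**: Gaussian peak at day 4, width 2.5; in the center on days 7–16
  the profile is `1.15·f + 0.1` — scaled and offset so that the
  characteristic persistence of center inflammation through resolution is a
  deterministic feature rather than a noise-level one (a pure multiplier on
  a near-zero Gaussian tail would vanish below replicate noise by day ~11).
- **ecm**: `−0.6·e^{−t/1.5} + 0.9·(1 − e^{−t/8})` — day-1 dip, slow rise.
- **epithelial**: edge ≡ 1; center 1 at day 0, then `1 − 0.9·e^{−(t−1)/6}`
  — the day-1 drop and gradual recovery of keratinization at the center.
- **tissue_dev**: `1 − e^{−t/2}` — early rise, stable plateau.
- **cell_cycle**: Gaussian peak at day 4, width 1.5, minus (center only) a
  sharp day-1 dip `0.5·e^{−(t−1)²/0.5}`.
- **hair / muscle / lipid**: per-sample 0/1 burst indicators in place of a
  temporal profile. Muscle uses a fixed assignment — exactly 6 of the 30
  day 1–5 center samples (one per day plus a second on day 3) — making the
  6-of-30 heterogeneity count exact; hair bursts in edge samples with
  probability 0.5 and lipid in day 1–3 center samples with probability 0.2
  (seeded Bernoulli, topped up deterministically to at least 2 positives so
  each program is identifiable in every realization).

Two day-3 wounds (chosen among wounds without fixed muscle positives) have
their center sample replaced by the paired edge sample plus N(0, 0.05)
noise, recorded as duplicate pairs; the duplicated center inherits the
edge's contamination status, since it is physically the same tissue.

Default gene counts: 30 genes per non-background archetype (comfortably
above the N > 10 retention rule), 400 background genes with amplitude 0 and
baselines uniform in [2, 10]. Archetype baselines are uniform [2, 4]
shifted by `−A_i·min(f, 0)` so profiles stay in range and clipping is rare.

`noise_sd` defaults to 0.15 log2 units and `tissue_jitter_sd` to 0.15.
These were fixed by design-time analysis of the planted correlation
structure: gene-level noise must stay below ~0.2 so that sparse burst
clusters (lipid can have as few as 2 positive samples out of 146) keep
within-cluster Pearson correlations above the 0.9 admission threshold,
while the largest cross-archetype profile correlations (immune vs
cell-cycle and ecm vs tissue-development, ≈ 0.86 over this design) stay
safely below it. Real bulk replicates are noisier and less block-structured
than this; passing recovery tests on these data demonstrates that the
procedure is implemented correctly and behaves as intended on data with
clean planted structure, not that it will resolve weaker or overlapping
programs in real tissue.

What the generator does **not** emulate: count-level sampling noise and
library-size effects (simulation is at the log-expression level the
analysis consumes), gene-gene correlation within the background, partially
overlapping programs, batch or animal effects, and real gene identities
(a few representative symbols — KRT1, KRT27, TNN, RETSAT — are attached as
labels only).

## Numerical choices and degenerate inputs

- Correlations are computed as dot products of population-z-scored rows;
  this matches the two-pass product-moment formula to ~1e-15.
- Strict inequalities throughout (`dG > 4`, `c > 0.9`, `N > 10`): a gene at
  exactly the threshold is excluded, a 10-gene cluster is dropped, a
  candidate at exactly the admission threshold is not admitted.
- Ties/order: cluster discovery order is input gene order; permuting gene
  order may legitimately change the clustering (documented, not asserted).
- Empty matrix → empty cluster list; empty schedule → empty metadata;
  single-day trajectories are one-point paths; groups with zero samples are
  omitted from summaries.
- Constant genes: error (by name) in standardization; correlation 0 with a
  warning as cluster candidates; impossible after the dG filter.

## Known limitations

- The greedy procedure is order-dependent and has no optimality guarantee;
  it is implemented as specified because its simplicity and auditability
  are the point, with a brute-force twin used for verification in tests.
- Hypergeometric overlap probabilities are descriptive (no multiple-testing
  correction), matching their qualitative use.
- No normalization or batch correction is provided; inputs are assumed
  comparably scaled across samples.
- Problem sizes in tests and the acceptance script are the defaults above
  (640 genes × 150 samples, 10 seeds where multi-seed behavior is
  asserted); the pipeline is O(genes × samples) per clustering pass and
  runs in well under a second at this scale.
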