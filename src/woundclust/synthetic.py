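"""Seeded synthetic wound-healing expression data with planted ground truth.

The generator emulates the design of a porcine excisional wound time course:
150 biopsies over 15 time points (days 0-21), two sampling locations per
wound (edge and center) plus unwounded day-0 baseline tissue, and a set of
co-expressed gene programs ("archetypes") whose temporal/spatial shapes match
the major programs seen in acute wound healing — immune activation, ECM
remodeling, epithelial repair, tissue development, cell cycle — together with
bursty tissue-capture programs (hair follicle, muscle, lipid) that reflect
biopsy-composition heterogeneity rather than temporal biology.

All values live on the log2(1 + expression) scale, clipped to [0, 20].
Every gene's archetype, every contamination event, and the two planted
near-duplicate edge-center pairs are recorded in :class:`SyntheticTruth`
so downstream recovery can be tested exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignSchedule",
    "ArchetypeSpec",
    "SyntheticTruth",
    "DgMarginReport",
    "default_schedule",
    "default_archetypes",
    "expand_design",
    "archetype_profile",
    "generate_dataset",
    "verify_dg_margins",
]

LOCATIONS = ("edge", "center", "baseline")

ARCHETYPE_NAMES = (
    "immune",
    "ecm",
    "epithelial",
    "tissue_dev",
    "cell_cycle",
    "hair",
    "muscle",
    "lipid",
    "background",
)

#: archetypes whose expression is driven by per-sample tissue-capture bursts
BURST_ARCHETYPES = ("hair", "muscle", "lipid")

#: symbolic labels for one representative gene per archetype (labels only)
REPRESENTATIVE_SYMBOLS = {
    "epithelial": "KRT1",
    "hair": "KRT27",
    "muscle": "TNN",
    "lipid": "RETSAT",
}


@dataclass(frozen=True)
class DesignSchedule:
    """Sampling schedule: (day, location, replicates) entries."""

    entries: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for day, loc, reps in self.entries:
            if loc not in LOCATIONS:
                raise ValueError(f"unknown location {loc!r} in schedule entry")
            if day < 0 or reps < 1:
                raise ValueError(f"invalid schedule entry {(day, loc, reps)}")
            if loc == "baseline" and day != 0:
                raise ValueError("baseline entries must have day 0")
            if (day, loc) in seen:
                raise ValueError(f"duplicate schedule entry for {(day, loc)}")
            seen.add((day, loc))

    @property
    def n_samples(self) -> int:
        return sum(r for _, _, r in self.entries)

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted({d for d, _, _ in self.entries}))

    def count(self, location: str) -> int:
        return sum(r for _, loc, r in self.entries if loc == location)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted gene program.

    ``amplitude_range`` is in log2 units; the per-gene amplitude ``A_i`` is
    drawn uniformly from it.  Non-background archetypes must have a low bound
    of at least 5 so that every planted gene clears the dG > 4 dynamic-range
    filter with margin.  ``params`` tunes the temporal profile (see
    :func:`archetype_profile`).
    """

    name: str
    n_genes: int
    amplitude_range: tuple[float, float] = (5.0, 8.0)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(f"unknown archetype name {self.name!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.amplitude_range
        if self.name == "background":
            if not (lo == hi == 0.0):
                raise ValueError("background amplitude must be 0")
        elif lo < 5.0:
            raise ValueError(
                f"non-background archetype {self.name!r} needs amplitude >= 5 "
                "(dG > 4 margin)"
            )
        if hi < lo:
            raise ValueError("amplitude_range must be (low, high) with high >= low")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    gene_archetype: dict[str, str]
    #: sample_id -> {burst archetype -> present}
    contamination: dict[str, dict[str, bool]]
    #: (edge sample id, center sample id) pairs planted as near-duplicates
    duplicate_pairs: list[tuple[str, str]]

    def members(self, archetype: str) -> list[str]:
        return [g for g, a in self.gene_archetype.items() if a == archetype]

    def non_background_genes(self) -> list[str]:
        return [g for g, a in self.gene_archetype.items() if a != "background"]

    def contaminated_samples(self, archetype: str) -> list[str]:
        return [s for s, d in self.contamination.items() if d.get(archetype, False)]

    def to_json(self, path) -> None:
        payload = {
            "gene_archetype": self.gene_archetype,
            "contamination": self.contamination,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            gene_archetype=payload["gene_archetype"],
            contamination={
                s: {a: bool(v) for a, v in d.items()}
                for s, d in payload["contamination"].items()
            },
            duplicate_pairs=[tuple(p) for p in payload["duplicate_pairs"]],
        )


def default_schedule() -> DesignSchedule:
    """The study design: 150 samples over 15 time points.

    Six unwounded baseline samples on day 0; six replicates per location on
    days 1-7, 9, 11 and 13; three per location on days 15, 16, 19 and 21.
    """
    entries: list[tuple[int, str, int]] = [(0, "baseline", 6)]
    for day in (1, 2, 3, 4, 5, 6, 7, 9, 11, 13):
        entries += [(day, "edge", 6), (day, "center", 6)]
    for day in (15, 16, 19, 21):
        entries += [(day, "edge", 3), (day, "center", 3)]
    return DesignSchedule(tuple(entries))


def default_archetypes(
    n_genes_per_archetype: int = 30, n_background: int = 400
) -> list[ArchetypeSpec]:
    """Eight planted programs of 30 genes each plus 400 background genes."""
    specs = [
        ArchetypeSpec(name, n_genes_per_archetype)
        for name in ARCHETYPE_NAMES
        if name != "background"
    ]
    specs.append(ArchetypeSpec("background", n_background, (0.0, 0.0)))
    return specs


def expand_design(
    schedule: DesignSchedule, n_pigs: int = 6, wounds_per_pig: int = 12
) -> pd.DataFrame:
    """Expand a schedule into per-sample metadata.

    Edge and center replicates with the same (day, replicate index) share a
    wound id, which defines the edge-center pairing. Pigs are assigned
    round-robin over replicate indices.
    """
    for day, loc, reps in schedule.entries:
        if reps > n_pigs * wounds_per_pig:
            raise ValueError(
                f"schedule entry {(day, loc, reps)} needs more wounds than "
                f"{n_pigs} pigs x {wounds_per_pig} wounds provide"
            )
    rows = []
    for day, loc, reps in schedule.entries:
        for i in range(reps):
            pig = f"P{(i % n_pigs) + 1}"
            if loc == "baseline":
                wound = f"{pig}BL{i + 1}"
            else:
                wound = f"D{day:02d}W{i + 1}"
            rows.append(
                {
                    "sample_id": f"d{day:02d}_{loc}_{i + 1}",
                    "pig": pig,
                    "wound": wound,
                    "day": day,
                    "location": loc,
                }
            )
    meta = pd.DataFrame(rows, columns=["sample_id", "pig", "wound", "day", "location"])
    return meta


def archetype_profile(name: str, params: dict | None, day: float, location: str) -> float:
    """Deterministic latent profile value for one archetype at (day, location).

    Values are nominally in [-1, 1].  The baseline location represents healthy
    unwounded tissue: epithelial programs are fully on (1), everything else is
    at its resting level (0).  Burst archetypes (hair/muscle/lipid) return the
    nominal burst height 1; the per-sample burst indicator is applied by
    :func:`generate_dataset`.
    """
    if name not in ARCHETYPE_NAMES:
        raise ValueError(f"unknown archetype name {name!r}")
    if location not in LOCATIONS:
        raise ValueError(f"unknown location {location!r}")
    p = params or {}
    t = float(day)

    if location == "baseline":
        return 1.0 if name == "epithelial" else 0.0

    if name == "background":
        return 0.0
    if name in BURST_ARCHETYPES:
        return 1.0
    if name == "immune":
        peak = p.get("peak_day", 4.0)
        width = p.get("width", 2.5)
        f = math.exp(-((t - peak) ** 2) / (2 * width**2))
        lo, hi = p.get("center_boost_days", (7.0, 16.0))
        if location == "center" and lo <= t <= hi:
            # center stays elevated through resolution: scaled + offset so the
            # center-vs-edge difference survives the decaying tail
            f = p.get("center_boost_scale", 1.15) * f + p.get("center_boost_add", 0.1)
        return f
    if name == "ecm":
        dip = p.get("dip_depth", 0.6)
        dip_tau = p.get("dip_tau", 1.5)
        rise = p.get("rise_level", 0.9)
        rise_tau = p.get("rise_tau", 8.0)
        return -dip * math.exp(-t / dip_tau) + rise * (1 - math.exp(-t / rise_tau))
    if name == "epithelial":
        if location == "edge" or t < 1:
            return 1.0
        drop = p.get("drop_depth", 0.9)
        tau = p.get("recovery_tau", 6.0)
        return 1.0 - drop * math.exp(-max(t - 1.0, 0.0) / tau)
    if name == "tissue_dev":
        tau = p.get("rise_tau", 2.0)
        return 1.0 - math.exp(-t / tau)
    if name == "cell_cycle":
        peak = p.get("peak_day", 4.0)
        width = p.get("width", 1.5)
        f = math.exp(-((t - peak) ** 2) / (2 * width**2))
        if location == "center":
            depth = p.get("center_dip_depth", 0.5)
            dip_day = p.get("center_dip_day", 1.0)
            dip_var = p.get("center_dip_var", 0.5)
            f -= depth * math.exp(-((t - dip_day) ** 2) / dip_var)
        return f
    raise AssertionError("unreachable")


def _burst_indicators(
    meta: pd.DataFrame,
    rng: np.random.Generator,
    hair_edge_p: float,
    lipid_center_p: float,
    muscle_edge_positives: int,
    min_bursts: int,
) -> dict[str, np.ndarray]:
    """Per-sample burst indicators for the three tissue-capture archetypes.

    Muscle uses a fixed assignment — exactly 6 of the 30 center samples on
    days 1-5 (replicate 1 of each day plus replicate 2 of day 3) — so the
    6-of-30 heterogeneity observation is deterministic. Hair and lipid use
    seeded Bernoulli draws, topped up to ``min_bursts`` positives so each
    program is identifiable in every seeded realization.
    """
    n = len(meta)
    day = meta["day"].to_numpy()
    loc = meta["location"].to_numpy()
    rep = meta.groupby(["day", "location"], sort=False).cumcount().to_numpy() + 1

    muscle = np.zeros(n, dtype=bool)
    muscle |= (loc == "center") & (day >= 1) & (day <= 5) & (rep == 1)
    muscle |= (loc == "center") & (day == 3) & (rep == 2)
    if muscle_edge_positives > 0:
        eligible = np.flatnonzero((loc == "edge") & (day >= 1) & (day <= 5))
        muscle[eligible[:muscle_edge_positives]] = True

    hair = (loc == "edge") & (rng.random(n) < hair_edge_p)
    lipid = (loc == "center") & (day >= 1) & (day <= 3) & (rng.random(n) < lipid_center_p)
    for ind, mask in (
        (hair, loc == "edge"),
        (lipid, (loc == "center") & (day >= 1) & (day <= 3)),
    ):
        eligible = np.flatnonzero(mask)
        k = min(min_bursts, eligible.size)
        if ind.sum() < k:
            ind[eligible[: k]] = True
    return {"hair": hair, "muscle": muscle, "lipid": lipid}


def generate_dataset(
    schedule: DesignSchedule | None = None,
    archetypes: list[ArchetypeSpec] | None = None,
    noise_sd: float = 0.15,
    seed: int | None = None,
    *,
    n_pigs: int = 6,
    wounds_per_pig: int = 12,
    tissue_jitter_sd: float = 0.15,
    plant_duplicates: bool = True,
    duplicate_noise_sd: float = 0.05,
    duplicate_day: int = 3,
    hair_edge_p: float = 0.5,
    lipid_center_p: float = 0.2,
    muscle_edge_positives: int = 0,
    min_bursts: int = 2,
    clip: tuple[float, float] = (0.0, 20.0),
    symbolic_names: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate an expression matrix, sample metadata, and ground truth.

    The model per gene i and sample j is

        g_ij = baseline_i + A_i * gamma_{a(i),j} * f_{a(i)}(day_j, loc_j) + eps_ij

    with ``eps ~ Normal(0, noise_sd)``, per-gene amplitude ``A_i`` uniform in
    the archetype's amplitude range, and ``gamma`` a per-(sample, archetype)
    tissue-composition factor ``max(0, Normal(1, tissue_jitter_sd))`` shared by
    all genes of one program (biopsies capture variable fractions of each
    tissue program).  Burst archetypes replace ``f`` with a per-sample 0/1
    indicator.  Two wounds on ``duplicate_day`` have their center sample
    replaced by the paired edge sample plus ``Normal(0, duplicate_noise_sd)``
    noise, emulating two biopsies taken from nearly the same site.  Values are
    clipped to [0, 20].
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    schedule = schedule or default_schedule()
    archetypes = archetypes if archetypes is not None else default_archetypes()
    if not archetypes:
        raise ValueError("need at least one archetype")

    rng = np.random.default_rng(seed)
    meta = expand_design(schedule, n_pigs=n_pigs, wounds_per_pig=wounds_per_pig)
    n_samples = len(meta)

    bursts = _burst_indicators(
        meta, rng, hair_edge_p, lipid_center_p, muscle_edge_positives, min_bursts
    )

    # latent profile per archetype per sample
    latent: dict[str, np.ndarray] = {}
    for spec in archetypes:
        f = np.array(
            [
                archetype_profile(spec.name, spec.params, d, l)
                for d, l in zip(meta["day"], meta["location"])
            ]
        )
        if spec.name in BURST_ARCHETYPES:
            f = f * bursts[spec.name]
        latent[spec.name] = f

    gene_ids: list[str] = []
    gene_arch: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    prefix = {
        "immune": "IMM",
        "ecm": "ECM",
        "epithelial": "EPI",
        "tissue_dev": "TDV",
        "cell_cycle": "CCY",
        "hair": "HAIR",
        "muscle": "MUS",
        "lipid": "LIP",
        "background": "BG",
    }
    for spec in archetypes:
        f = latent[spec.name]
        fmin = min(float(f.min()), 0.0)
        if spec.name in BURST_ARCHETYPES or spec.name == "background":
            jitter = np.ones(n_samples)
        else:
            jitter = np.maximum(rng.normal(1.0, tissue_jitter_sd, n_samples), 0.0)
        for g in range(spec.n_genes):
            amp = rng.uniform(*spec.amplitude_range)
            if spec.name == "background":
                base = rng.uniform(2.0, 10.0)
            else:
                base = rng.uniform(2.0, 4.0) - amp * fmin
            row = base + amp * jitter * f + rng.normal(0.0, noise_sd, n_samples)
            blocks.append(row)
            if g == 0 and symbolic_names and spec.name in REPRESENTATIVE_SYMBOLS:
                gid = REPRESENTATIVE_SYMBOLS[spec.name]
            else:
                gid = f"{prefix[spec.name]}{g + 1:04d}"
            gene_ids.append(gid)
            gene_arch[gid] = spec.name

    values = np.clip(np.vstack(blocks), *clip)
    matrix = pd.DataFrame(values, index=gene_ids, columns=meta["sample_id"].tolist())
    matrix.index.name = "gene_id"

    contamination = {
        sid: {a: bool(bursts[a][j]) for a in BURST_ARCHETYPES}
        for j, sid in enumerate(meta["sample_id"])
    }

    duplicate_pairs: list[tuple[str, str]] = []
    if plant_duplicates:
        day_mask = meta["day"] == duplicate_day
        edges = meta[day_mask & (meta["location"] == "edge")]
        centers = meta[day_mask & (meta["location"] == "center")]
        paired = pd.merge(edges, centers, on="wound", suffixes=("_e", "_c"))
        # use the last wounds of the day so fixed muscle positives (first
        # replicates) are never overwritten by the duplication
        mus_centers = {s for s, d in contamination.items() if d["muscle"]}
        candidates = [
            (r.sample_id_e, r.sample_id_c)
            for r in paired.itertuples()
            if r.sample_id_c not in mus_centers
        ]
        if len(candidates) < 2:
            raise ValueError(
                f"schedule lacks day-{duplicate_day} edge/center pairs for "
                "duplicate planting"
            )
        for e_id, c_id in candidates[-2:]:
            e_col = matrix.columns.get_loc(e_id)
            c_col = matrix.columns.get_loc(c_id)
            values[:, c_col] = np.clip(
                values[:, e_col] + rng.normal(0.0, duplicate_noise_sd, values.shape[0]),
                *clip,
            )
            # the duplicated center is physically the same tissue as the edge
            contamination[c_id] = dict(contamination[e_id])
            duplicate_pairs.append((e_id, c_id))
        matrix = pd.DataFrame(values, index=gene_ids, columns=matrix.columns)
        matrix.index.name = "gene_id"

    truth = SyntheticTruth(gene_arch, contamination, duplicate_pairs)
    return matrix, meta, truth


@dataclass
class DgMarginReport:
    """Outcome of the planted dynamic-range margin check."""

    threshold: float
    violating_genes: list[str]

    @property
    def passed(self) -> bool:
        return not self.violating_genes


def verify_dg_margins(
    matrix: pd.DataFrame, truth: SyntheticTruth, threshold: float = 4.0
) -> DgMarginReport:
    """Check that planted genes sit strictly across the dG threshold.

    Every non-background gene must have dG (max - min over all samples)
    strictly above ``threshold``; every background gene strictly below.
    Report-only: returns the violating gene ids (empty under defaults).
    """
    dg = matrix.max(axis=1) - matrix.min(axis=1)
    violations = []
    for gene, arch in truth.gene_archetype.items():
        if gene not in dg.index:
            continue
        if arch == "background":
            if dg[gene] >= threshold:
                violations.append(gene)
        elif dg[gene] <= threshold:
            violations.append(gene)
    return DgMarginReport(threshold=threshold, violating_genes=violations)
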