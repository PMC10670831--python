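"""Synthetic cohort generator with planted ground truth.

Emulates the study design: 38 finishing pigs from 9 litters split into
balanced stress/control groups (every litter represented in both groups),
sampled at three gut sites.  Genus counts arise from a log-normal latent
abundance model (genus baseline + treatment shift for planted genera +
per-litter random effect + animal noise) pushed through multinomial sampling
at a fixed library depth, with one dominant Prevotella-like genus and a small
heavy-tailed "susceptible" subpopulation for designated pathogen genera.

The baseline abundance decay is calibrated so the realized zero fraction of
the count matrix matches a target sparsity (default 57%).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import GenusCountTable, SITES, write_count_table, write_metadata

logger = logging.getLogger(__name__)

DEFAULT_PATHOGENS = ("Clostridium", "Treponema", "Streptococcus", "Campylobacter")
#: baseline-rank positions of the four pathogen genera (after the dominant genus)
_PATHOGEN_RANKS = (3, 6, 9, 12)
_DOMINANT_GENUS = "Prevotella"
_DOMINANT_TARGET = 0.33  # mean relative abundance of the dominant genus


def genus_names(n_genera: int, pathogens: tuple[str, ...] = DEFAULT_PATHOGENS) -> list[str]:
    """Genus id list: dominant genus first, pathogens at fixed ranks, filler ids."""
    if n_genera < max(_PATHOGEN_RANKS) + 2:
        raise ValueError(f"n_genera must be >= {max(_PATHOGEN_RANKS) + 2}")
    names = [f"Genus_{i:03d}" for i in range(n_genera)]
    names[0] = _DOMINANT_GENUS
    for rank, name in zip(_PATHOGEN_RANKS, pathogens):
        names[rank] = name
    return names


@dataclass(frozen=True)
class CohortDesign:
    """Structural parameters of a synthetic study."""

    n_animals: int = 38
    n_litters: int = 9
    sites: tuple[str, ...] = SITES
    n_genera: int = 60
    library_depth: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2 * self.n_litters:
            raise ValueError("need >=2 animals per litter so every litter spans both groups")
        if self.n_genera < 15:
            raise ValueError("n_genera must be >= 15")


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic cohort.

    Effect sizes are clr-scale shifts expressed in units of the total
    animal-level latent SD, sqrt(litter_sd^2 + residual_sd^2).
    """

    enriched: dict[str, float] = field(default_factory=dict)
    depleted: dict[str, float] = field(default_factory=dict)
    pathogens: tuple[str, ...] = DEFAULT_PATHOGENS
    susceptible: dict[str, frozenset[str]] = field(default_factory=dict)
    litter_sd: float = 0.15
    residual_sd: float = 0.3
    sparsity_target: float = 0.57
    susceptible_boost: float = 8.0

    def __post_init__(self) -> None:
        overlap = set(self.enriched) & set(self.depleted)
        if overlap:
            raise ValueError(f"genera both enriched and depleted: {sorted(overlap)}")
        for d in (self.enriched, self.depleted):
            for g, eff in d.items():
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite effect size for genus {g!r}")

    @property
    def latent_sd(self) -> float:
        return float(np.hypot(self.litter_sd, self.residual_sd))


def animal_ids(design: CohortDesign) -> list[str]:
    return [f"A{i:02d}" for i in range(design.n_animals)]


def make_metadata(design: CohortDesign) -> pd.DataFrame:
    """Deterministic sample metadata honouring the design invariants.

    Litters are filled round-robin; treatments alternate within litter with a
    global toggle so that group sizes differ by at most one and every litter
    contributes to both groups.  Pens of up to 4 animals are nested within
    treatment groups.
    """
    ids = animal_ids(design)
    litters = [f"L{i % design.n_litters + 1}" for i in range(design.n_animals)]
    treatment = [""] * design.n_animals
    toggle = 0
    for lit in dict.fromkeys(litters):  # litters in first-appearance order
        members = [i for i, l in enumerate(litters) if l == lit]
        for k, i in enumerate(members):
            treatment[i] = "stress" if (toggle + k) % 2 == 0 else "control"
        toggle += len(members)
    # global toggle keeps |n_stress - n_control| <= 1 by construction
    pens = [""] * design.n_animals
    for group in ("stress", "control"):
        members = [i for i, t in enumerate(treatment) if t == group]
        for k, i in enumerate(members):
            pens[i] = f"P{group[0].upper()}{k // 4 + 1}"
    rows = []
    for site in design.sites:
        for i, aid in enumerate(ids):
            rows.append(
                {
                    "sample_id": f"{aid}_{site}",
                    "animal_id": aid,
                    "treatment": treatment[i],
                    "litter": litters[i],
                    "pen": pens[i],
                    "site": site,
                }
            )
    return pd.DataFrame(rows)


def default_truth(
    design: CohortDesign,
    n_enriched: int = 5,
    n_depleted: int = 5,
    effect_size: float = 1.5,
    n_susceptible: int = 4,
    litter_sd: float = 0.15,
    residual_sd: float = 0.3,
    sparsity_target: float = 0.57,
    susceptible_boost: float = 8.0,
    seed: int | None = None,
) -> PlantedTruth:
    """Planted truth with effects on moderately abundant, non-pathogen genera."""
    names = genus_names(design.n_genera)
    candidates = [n for i, n in enumerate(names) if 1 <= i <= 20 and i not in _PATHOGEN_RANKS]
    if len(candidates) < n_enriched + n_depleted:
        raise ValueError("not enough candidate genera for the requested planted effects")
    enriched = {g: effect_size for g in candidates[:n_enriched]}
    depleted = {g: effect_size for g in candidates[n_enriched : n_enriched + n_depleted]}
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ids = animal_ids(design)
    susceptible = {
        p: frozenset(rng.choice(ids, size=n_susceptible, replace=False))
        for p in DEFAULT_PATHOGENS
    }
    return PlantedTruth(
        enriched=enriched,
        depleted=depleted,
        susceptible=susceptible,
        litter_sd=litter_sd,
        residual_sd=residual_sd,
        sparsity_target=sparsity_target,
        susceptible_boost=susceptible_boost,
    )


def null_truth(design: CohortDesign, **kwargs) -> PlantedTruth:
    """Truth with no planted effects and no susceptible animals."""
    return PlantedTruth(**kwargs)


def _baselines(tau: float, n_genera: int, dom_adjust: float = 0.0) -> np.ndarray:
    """Exponentially decaying log-baselines with a dominant first genus."""
    b = -tau * np.arange(n_genera, dtype=float)
    rest = np.exp(b[1:]).sum()
    b[0] = np.log(_DOMINANT_TARGET / (1.0 - _DOMINANT_TARGET) * rest) + dom_adjust
    return b


def _latent_proportions(
    b: np.ndarray,
    design: CohortDesign,
    truth: PlantedTruth,
    rng: np.random.Generator,
    shift: np.ndarray | None = None,
) -> np.ndarray:
    n_rep = 4
    eta = b + rng.normal(0.0, truth.latent_sd, size=(n_rep * design.n_animals, b.size))
    if shift is not None:  # half the replicate animals are "stressed"
        eta[::2] += shift
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return p


def calibrate_baselines(
    design: CohortDesign, truth: PlantedTruth, shift: np.ndarray | None = None
) -> np.ndarray:
    """Tune the baseline decay (sparsity target) and dominant-genus mass.

    Two interleaved bisections against Monte-Carlo expectations under the
    latent noise: the decay rate tau controls the expected zero fraction of
    the count matrix, and an additive adjustment on the dominant genus'
    log-baseline compensates the log-normal inflation of rare genera so its
    expected mean relative abundance stays near the dominance target.
    """
    rng = np.random.default_rng([design.seed, 424242])
    dom_adjust = 0.0
    tau = 0.3
    for _ in range(3):
        lo, hi = 0.01, 3.0

        def zero_frac(t: float) -> float:
            p = _latent_proportions(
                _baselines(t, design.n_genera, dom_adjust), design, truth, rng, shift
            )
            return float(np.mean(np.exp(-design.library_depth * p)))

        if not (zero_frac(lo) <= truth.sparsity_target <= zero_frac(hi)):
            raise ValueError(
                f"sparsity target {truth.sparsity_target} outside attainable range"
            )
        for _ in range(30):
            tau = 0.5 * (lo + hi)
            if zero_frac(tau) < truth.sparsity_target:
                lo = tau
            else:
                hi = tau

        d_lo, d_hi = 0.0, 3.0

        def dom_mass(adj: float) -> float:
            p = _latent_proportions(_baselines(tau, design.n_genera, adj), design, truth, rng, shift)
            return float(p[:, 0].mean())

        if dom_mass(d_hi) < _DOMINANT_TARGET:
            dom_adjust = d_hi
        else:
            for _ in range(25):
                dom_adjust = 0.5 * (d_lo + d_hi)
                if dom_mass(dom_adjust) < _DOMINANT_TARGET:
                    d_lo = dom_adjust
                else:
                    d_hi = dom_adjust
    return _baselines(tau, design.n_genera, dom_adjust)


def generate_counts(
    design: CohortDesign, truth: PlantedTruth
) -> tuple[dict[str, GenusCountTable], pd.DataFrame]:
    """Simulate genus count tables for every site plus the metadata table.

    Returns a mapping site -> GenusCountTable (rows = samples of that site)
    and the full sample metadata frame.
    """
    meta = make_metadata(design)
    names = genus_names(design.n_genera)
    name_to_idx = {n: i for i, n in enumerate(names)}
    for g in list(truth.enriched) + list(truth.depleted) + list(truth.pathogens):
        if g not in name_to_idx:
            raise ValueError(f"planted genus {g!r} not among generated genus ids")

    shift = np.zeros(design.n_genera)
    for g, eff in truth.enriched.items():
        shift[name_to_idx[g]] = eff * truth.latent_sd
    for g, eff in truth.depleted.items():
        shift[name_to_idx[g]] = -eff * truth.latent_sd
    if not np.isfinite(shift).all():
        raise ValueError("planted effect sizes produce non-finite latent shifts")

    b = calibrate_baselines(design, truth, shift)

    rng = np.random.default_rng(design.seed)
    ids = animal_ids(design)
    animal_meta = meta.drop_duplicates("animal_id").set_index("animal_id")
    litter_levels = list(dict.fromkeys(animal_meta["litter"]))

    boost = np.zeros((design.n_animals, design.n_genera))
    for p, animals in truth.susceptible.items():
        j = name_to_idx[p]
        for a in animals:
            boost[ids.index(a), j] = np.log(truth.susceptible_boost)

    tables: dict[str, GenusCountTable] = {}
    zero_cells = total_cells = 0
    for site in design.sites:
        u = rng.normal(0.0, truth.litter_sd, size=(len(litter_levels), design.n_genera))
        counts = np.empty((design.n_animals, design.n_genera), dtype=np.int64)
        for i, aid in enumerate(ids):
            row = animal_meta.loc[aid]
            eta = (
                b
                + (shift if row["treatment"] == "stress" else 0.0)
                + boost[i]
                + u[litter_levels.index(row["litter"])]
                + rng.normal(0.0, truth.residual_sd, size=design.n_genera)
            )
            if not np.isfinite(eta).all():
                raise ValueError("latent abundances are non-finite; check effect sizes")
            p = np.exp(eta - eta.max())
            p /= p.sum()
            counts[i] = rng.multinomial(design.library_depth, p)
        df = pd.DataFrame(counts, index=[f"{a}_{site}" for a in ids], columns=names)
        tables[site] = GenusCountTable(df, site=site)
        zero_cells += int((counts == 0).sum())
        total_cells += counts.size
    realized = zero_cells / total_cells
    if abs(realized - truth.sparsity_target) > 0.10:
        warnings.warn(
            f"realized zero fraction {realized:.3f} deviates from target "
            f"{truth.sparsity_target:.2f} by more than 0.10",
            stacklevel=2,
        )
    return tables, meta


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

#: relative lesion load of the six body zones (front/middle/rear x left/right)
_ZONE_WEIGHTS = {
    "front_left": 0.20,
    "front_right": 0.20,
    "middle_left": 0.175,
    "middle_right": 0.175,
    "rear_left": 0.125,
    "rear_right": 0.125,
}
CORTISOL_HOURS = (7, 10, 13, 16)
_CORTISOL_SHAPE = np.array([1.5, 1.2, 0.9, 0.6])  # morning-high circadian profile
TRIAL_DAYS = 28
LESION_WEEKS = (1, 2, 3, 4)
CORTISOL_WEEKS = (0, 2, 4)


@dataclass(frozen=True)
class PhenotypeEffects:
    """Additive stress-minus-control effects planted on the phenotype layer."""

    dfi: float = -0.35  # kg/day
    adg: float = -0.21  # kg/day
    cortisol_auc: float = 107.0  # conc*h per sampling day (trial weeks)
    lesions: float = 60.0  # weekly total lesion count

    # control-group baselines
    dfi_base: float = 2.79
    adg_base: float = 1.33
    cortisol_base: float = 192.0
    lesions_base: float = 44.0
    weight_base: float = 80.0


def generate_phenotypes(
    design: CohortDesign,
    truth: PlantedTruth,
    effects: PhenotypeEffects = PhenotypeEffects(),
) -> pd.DataFrame:
    """Simulate the per-animal phenotype table.

    Columns: animal id/pen, weekly weights ``weight_wk0..4`` (the endpoint is
    exact in the latent ADG so growth recomputes it), the pen-level daily feed
    total (sum of latent individual intakes), lesion counts per trial week and
    body zone, and 4-point cortisol profiles for sampling weeks 0/2/4.
    """
    rng = np.random.default_rng([design.seed, 777])
    meta = make_metadata(design).drop_duplicates("animal_id").set_index("animal_id")
    ids = animal_ids(design)
    litter_levels = list(dict.fromkeys(meta["litter"]))
    lit_adg = rng.normal(0.0, 0.04, len(litter_levels))
    lit_dfi = rng.normal(0.0, 0.05, len(litter_levels))
    lit_cort = rng.normal(0.0, 8.0, len(litter_levels))
    lit_les = rng.normal(0.0, 3.0, len(litter_levels))

    rows = []
    for aid in ids:
        info = meta.loc[aid]
        stressed = info["treatment"] == "stress"
        li = litter_levels.index(info["litter"])
        adg = effects.adg_base + (effects.adg if stressed else 0.0) + lit_adg[li] + rng.normal(0, 0.08)
        adg = max(adg, 0.2)
        dfi = effects.dfi_base + (effects.dfi if stressed else 0.0) + lit_dfi[li] + rng.normal(0, 0.15)
        dfi = max(dfi, 0.5)
        w0 = effects.weight_base + rng.normal(0, 5.0)
        if w0 <= 0:
            raise ValueError("simulated starting weight is non-positive")
        weights = {f"weight_wk{k}": w0 + adg * 7 * k + (rng.normal(0, 0.3) if 0 < k < 4 else 0.0) for k in range(5)}
        weights["weight_wk4"] = w0 + adg * TRIAL_DAYS  # endpoint exact: ADG recoverable

        row = {"animal_id": aid, "pen": info["pen"], "_latent_dfi": dfi, "_latent_adg": adg}
        row.update(weights)

        for wk in LESION_WEEKS:
            lam_total = effects.lesions_base + (effects.lesions if stressed else 0.0)
            lam_total = max(lam_total + lit_les[li] + rng.normal(0, 6.0), 1.0)
            for zone, wz in _ZONE_WEIGHTS.items():
                row[f"lesions_wk{wk}_{zone}"] = int(rng.poisson(lam_total * wz))

        auc_shape = np.trapezoid(_CORTISOL_SHAPE, CORTISOL_HOURS)
        for wk in CORTISOL_WEEKS:
            target = effects.cortisol_base + lit_cort[li] + rng.normal(0, 25.0)
            if wk > 0 and stressed:
                target += effects.cortisol_auc
            level = max(target, 20.0) / auc_shape
            pts = np.maximum(level * _CORTISOL_SHAPE + rng.normal(0, level * 0.05, 4), 0.0)
            for h, v in zip(CORTISOL_HOURS, pts):
                row[f"cortisol_wk{wk}_h{h:02d}"] = round(float(v), 4)
        rows.append(row)

    df = pd.DataFrame(rows)
    pen_daily = df.groupby("pen")["_latent_dfi"].sum()
    df["pen_feed_daily_kg"] = df["pen"].map(pen_daily).round(6)
    df = df.drop(columns=["_latent_dfi", "_latent_adg"])
    for c in df.columns:
        if c.startswith("weight"):
            df[c] = df[c].round(4)
    return df


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    design: CohortDesign
    truth: PlantedTruth
    counts: dict[str, GenusCountTable]
    metadata: pd.DataFrame
    phenotypes: pd.DataFrame


def simulate_cohort(
    design: CohortDesign,
    truth: PlantedTruth | None = None,
    effects: PhenotypeEffects = PhenotypeEffects(),
) -> Cohort:
    if truth is None:
        truth = default_truth(design)
    counts, meta = generate_counts(design, truth)
    phen = generate_phenotypes(design, truth, effects)
    return Cohort(design, truth, counts, meta, phen)


def truth_to_dict(design: CohortDesign, truth: PlantedTruth) -> dict:
    d = dataclasses.asdict(design)
    d["sites"] = list(design.sites)
    return {
        "design": d,
        "enriched": truth.enriched,
        "depleted": truth.depleted,
        "pathogens": list(truth.pathogens),
        "susceptible": {p: sorted(a) for p, a in truth.susceptible.items()},
        "litter_sd": truth.litter_sd,
        "residual_sd": truth.residual_sd,
        "sparsity_target": truth.sparsity_target,
        "susceptible_boost": truth.susceptible_boost,
    }


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write counts_{site}.tsv, metadata.tsv, phenotypes.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for site, table in cohort.counts.items():
        write_count_table(table, outdir / f"counts_{site}.tsv")
    write_metadata(cohort.metadata, outdir / "metadata.tsv")
    cohort.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_to_dict(cohort.design, cohort.truth), fh, indent=2, sort_keys=True)
    logger.info("wrote synthetic cohort to %s", outdir)
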