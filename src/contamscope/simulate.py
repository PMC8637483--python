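"""Synthetic low-biomass amplicon study generator with ground truth.

Emulates the design of an individual-mosquito gut 16S study: three
replicates (collection campaign + blood donor), three blood treatments
(mock control, amoxicillin, amoxicillin + clavulanic acid), two dissection
timepoints (24 h / 72 h post blood meal), five specimens per cell (90
specimens total) and one extraction blank (PBS tube) per replicate.

The contamination model is the generator's core. Each specimen j carries a
microbial biomass ``B_j`` (log-normal); its reads are a multinomial draw
from the mixture ``w_j * true_j + (1 - w_j) * pool`` with
``w_j = B_j / (B_j + c0)``: the reagent-contaminant share of a library
rises as biomass falls. Negative controls draw from
``(1 - eps) * pool + eps * mean specimen mixture`` of their replicate,
where ``eps`` models cross-contamination of blanks by true samples.
Community and contaminant-pool taxa are disjoint, so every read's origin
is identifiable and classifier sensitivity/specificity can be scored
exactly.

Planted treatment effects multiply designated genus proportions by
``2**(-delta)`` (before renormalisation) in chosen treatment x timepoint
cells; infection-associated enrichments scale genera in the replicates fed
on gametocyte-carrying blood. Genus names reuse the four majors of the
motivating study system (Elizabethkingia, Wigglesworthia, Asaia, Serratia)
purely for readable fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_study", "generate_survival"]

TREATMENTS = ("control", "amox", "amox_clav")
TIMEPOINTS = (24, 72)

# community genera: (genus, n ASVs, target share of the mean community)
_COMMUNITY_PLAN = [
    ("Elizabethkingia", 8, 0.20),
    ("Wigglesworthia", 6, 0.17),
    ("Asaia", 8, 0.11),
    ("Serratia", 6, 0.13),
    ("Aeromonas", 4, 0.06),
    ("Comamonas", 4, 0.05),
    ("Cedecea", 3, 0.04),
    ("Heliimonas", 3, 0.03),
    ("Chryseobacterium", 4, 0.05),
    ("Pseudomonas", 4, 0.05),
    ("Acinetobacter", 4, 0.04),
    ("Enterobacter", 3, 0.04),
    (None, 3, 0.03),  # annotated to family only (Enterobacteriaceae)
]

_CONTAMINANT_GENERA = (
    "Ralstonia", "Sphingomonas", "Staphylococcus", "Rhizobium",
    "Bradyrhizobium", "Methylobacterium", "Burkholderia", "Cutibacterium",
)

_LINEAGE_PREFIX = {
    "Elizabethkingia": "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Weeksellaceae",
    "Wigglesworthia": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Erwiniaceae",
    "Asaia": "Bacteria;Proteobacteria;Alphaproteobacteria;Acetobacterales;Acetobacteraceae",
    "Serratia": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Yersiniaceae",
    "Aeromonas": "Bacteria;Proteobacteria;Gammaproteobacteria;Aeromonadales;Aeromonadaceae",
    "Comamonas": "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Comamonadaceae",
    "Cedecea": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae",
    "Heliimonas": "Bacteria;Bacteroidota;Chitinophagia;Chitinophagales;Chitinophagaceae",
    "Chryseobacterium": "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Weeksellaceae",
    "Pseudomonas": "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae",
    "Acinetobacter": "Bacteria;Proteobacteria;Gammaproteobacteria;Moraxellales;Moraxellaceae",
    "Enterobacter": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae",
    "Ralstonia": "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Burkholderiaceae",
    "Sphingomonas": "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae",
    "Staphylococcus": "Bacteria;Firmicutes;Bacilli;Staphylococcales;Staphylococcaceae",
    "Rhizobium": "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae",
    "Bradyrhizobium": "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Xanthobacteraceae",
    "Methylobacterium": "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Beijerinckiaceae",
    "Burkholderia": "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Burkholderiaceae",
    "Cutibacterium": "Bacteria;Actinobacteriota;Actinomycetia;Propionibacteriales;Propionibacteriaceae",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and contamination parameters for the generator.

    Defaults reproduce the emulated design: 3 replicates x 3 treatments x
    2 timepoints x 5 specimens = 90 specimens plus one blank per replicate.
    ``replicates`` maps replicate code to infection status of the donor
    blood. Biomass and read depth are log-normal (natural-log parameters);
    ``c0`` is the constant contaminant mass against which specimen biomass
    competes; ``cross_contamination_rate`` is the blank's share of leaked
    sample material.
    """

    replicates: dict = dc_field(default_factory=lambda: {
        "AP4": "uninfected", "BP3": "infected", "P10": "infected",
    })
    specimens_per_cell: int = 5
    n_controls_per_replicate: int = 1
    s_true: int = 60
    s_cont: int = 40
    replicate_concentration: float = 50.0
    specimen_concentration: float = 200.0
    mu_biomass: float = np.log(2.0)
    sigma_biomass: float = 0.8
    c0: float = 1.0
    cross_contamination_rate: float = 0.05
    mu_depth: float = np.log(30000.0)
    sigma_depth: float = 0.3
    min_depth: int = 500
    pool_concentration: float = 10.0
    planted_effects: tuple = (
        ("Elizabethkingia", "amox", 24, 2.0),
        ("Elizabethkingia", "amox_clav", 24, 2.0),
        ("Asaia", "amox_clav", 24, 2.0),
    )
    infection_effects: tuple = (("Elizabethkingia", 4.0),)
    seed: int = None

    def validate(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory for the generator")
        if not 0 <= self.cross_contamination_rate < 1:
            raise ValidationError("cross_contamination_rate must be in [0, 1)")
        if self.c0 < 0:
            raise ValidationError("c0 must be non-negative")
        if self.specimens_per_cell < 1 or self.s_true < 1 or self.s_cont < 0:
            raise ValidationError("sizes must be positive")
        community_genera = {g for g, _, _ in _COMMUNITY_PLAN if g}
        for genus, treatment, timepoint, delta in self.planted_effects:
            if genus not in community_genera:
                raise ValidationError(
                    f"planted effect on unknown community genus {genus!r}"
                )
            if treatment not in TREATMENTS or timepoint not in TIMEPOINTS:
                raise ValidationError(
                    f"planted effect cell ({treatment!r}, {timepoint!r}) "
                    "is not part of the design"
                )
            if delta < 0:
                raise ValidationError("planted log2 depletion must be >= 0")
        for genus, mult in self.infection_effects:
            if genus not in community_genera:
                raise ValidationError(
                    f"infection effect on unknown community genus {genus!r}"
                )
            if mult <= 0:
                raise ValidationError("infection multiplier must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated study.

    ``taxon_origin``: 'community' or 'contaminant' per taxon.
    ``sample_truth``: per sample — biomass, mixture weight w (0 for
    blanks), read depth.
    ``mixtures``: expected read-generating proportions per sample (taxa x
    samples); the pool columns of a specimen sum to exactly 1 - w.
    ``contaminant_pool``: the pool composition over contaminant taxa.
    """

    taxon_origin: pd.Series
    sample_truth: pd.DataFrame
    mixtures: pd.DataFrame
    contaminant_pool: pd.Series
    planted_effects: tuple

    def contaminant_taxa(self) -> list:
        return self.taxon_origin.index[self.taxon_origin == "contaminant"].tolist()

    def community_taxa(self) -> list:
        return self.taxon_origin.index[self.taxon_origin == "community"].tolist()


def _community_layout(s_true: int):
    """Assign community taxa to genera and mean shares; scale plan to s_true."""
    plan = _COMMUNITY_PLAN
    n_plan = sum(n for _, n, _ in plan)
    if s_true != n_plan:
        # rescale ASV counts proportionally, keeping at least 1 per genus
        scaled = [max(1, round(n * s_true / n_plan)) for _, n, _ in plan]
        while sum(scaled) > s_true:
            scaled[int(np.argmax(scaled))] -= 1
        while sum(scaled) < s_true:
            scaled[int(np.argmin(scaled))] += 1
        plan = [(g, k, w) for (g, _, w), k in zip(plan, scaled)]
    taxa, genera, shares = [], [], []
    idx = 0
    for genus, n_asv, share in plan:
        # mildly decreasing within-genus weights
        weights = np.array([1.0 / (r + 1) for r in range(n_asv)])
        weights = weights / weights.sum() * share
        for r in range(n_asv):
            idx += 1
            taxa.append(f"ASV{idx:04d}")
            genera.append(genus)
            shares.append(weights[r])
    shares = np.asarray(shares)
    return taxa, genera, shares / shares.sum()


def _taxonomy(community_taxa, community_genera, pool_taxa, pool_genera) -> TaxonomyTable:
    lineages = {}
    for tid, genus in zip(community_taxa, community_genera):
        if genus is None:
            lineages[tid] = _LINEAGE_PREFIX["Cedecea"].split(";")  # family-only
        else:
            lineages[tid] = (_LINEAGE_PREFIX[genus] + ";" + genus).split(";")
    for tid, genus in zip(pool_taxa, pool_genera):
        lineages[tid] = (_LINEAGE_PREFIX[genus] + ";" + genus).split(";")
    return TaxonomyTable(lineages)


def generate_study(config: SimulationConfig):
    """Generate (FeatureTable, SampleMetadata, TaxonomyTable, SyntheticTruth).

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    community_taxa, community_genera, base_shares = _community_layout(config.s_true)
    pool_taxa = [f"CONT{i + 1:03d}" for i in range(config.s_cont)]
    n_pool_genera = len(_CONTAMINANT_GENERA)
    pool_genus_of = [
        _CONTAMINANT_GENERA[i % n_pool_genera] for i in range(config.s_cont)
    ]
    all_taxa = community_taxa + pool_taxa
    taxonomy = _taxonomy(community_taxa, community_genera, pool_taxa, pool_genus_of)

    # contaminant pool composition: moderately even Dirichlet
    if config.s_cont > 0:
        q = rng.dirichlet(np.full(config.s_cont, config.pool_concentration))
    else:
        q = np.zeros(0)

    genus_idx = {}
    for i, g in enumerate(community_genera):
        genus_idx.setdefault(g, []).append(i)

    # replicate base compositions around the global mean
    rep_base = {}
    for rep, infection in config.replicates.items():
        base = rng.dirichlet(config.replicate_concentration * config.s_true * base_shares)
        if infection == "infected":
            for genus, mult in config.infection_effects:
                base[genus_idx[genus]] *= mult
            base = base / base.sum()
        rep_base[rep] = base

    planted = {}
    for genus, treatment, timepoint, delta in config.planted_effects:
        planted.setdefault((treatment, timepoint), []).append((genus, delta))

    samples, metadata_rows = [], []
    counts_cols, mixture_cols = {}, {}
    truth_rows = []
    rep_mixture_sum = {rep: np.zeros(len(all_taxa)) for rep in config.replicates}
    rep_n_specimens = {rep: 0 for rep in config.replicates}

    species_levels = ("gambiae", "coluzzii", "arabiensis", "ND")
    species_probs = (49 / 90, 11 / 90, 16 / 90, 14 / 90)

    for rep, infection in config.replicates.items():
        for treatment in TREATMENTS:
            for timepoint in TIMEPOINTS:
                for i in range(config.specimens_per_cell):
                    sid = f"{rep}_{treatment}_{timepoint}h_{i + 1}"
                    p = rng.dirichlet(config.specimen_concentration * config.s_true
                                      * rep_base[rep])
                    for genus, delta in planted.get((treatment, timepoint), []):
                        p[genus_idx[genus]] *= 2.0 ** (-delta)
                    p = p / p.sum()
                    biomass = rng.lognormal(config.mu_biomass, config.sigma_biomass)
                    denom = biomass + config.c0
                    w = biomass / denom if denom > 0 else 1.0
                    if config.s_cont:
                        mixture = np.concatenate([w * p, (1.0 - w) * q])
                    else:
                        # no pool taxa: all reads are community-origin
                        mixture = p
                    depth = max(int(rng.lognormal(config.mu_depth, config.sigma_depth)),
                                config.min_depth)
                    counts_cols[sid] = rng.multinomial(depth, mixture / mixture.sum())
                    mixture_cols[sid] = mixture / mixture.sum()
                    rep_mixture_sum[rep] += mixture_cols[sid]
                    rep_n_specimens[rep] += 1
                    samples.append(sid)
                    metadata_rows.append({
                        "sample_id": sid, "role": "specimen", "replicate": rep,
                        "treatment": treatment, "timepoint_h": timepoint,
                        "infection": infection,
                        "species": rng.choice(species_levels, p=species_probs),
                    })
                    truth_rows.append({
                        "sample_id": sid, "biomass": biomass, "w": w,
                        "depth": depth,
                    })

    eps = config.cross_contamination_rate
    for rep, infection in config.replicates.items():
        mean_mix = (rep_mixture_sum[rep] / rep_n_specimens[rep]
                    if rep_n_specimens[rep] else np.zeros(len(all_taxa)))
        pool_full = np.concatenate([np.zeros(len(community_taxa)), q]) \
            if config.s_cont else np.zeros(len(all_taxa))
        ctrl_mix = (1.0 - eps) * pool_full + eps * mean_mix
        for c in range(config.n_controls_per_replicate):
            sid = f"{rep}_ctrl{c + 1}"
            depth = max(int(rng.lognormal(config.mu_depth, config.sigma_depth)),
                        config.min_depth)
            if ctrl_mix.sum() > 0:
                counts_cols[sid] = rng.multinomial(depth, ctrl_mix / ctrl_mix.sum())
                mixture_cols[sid] = ctrl_mix / ctrl_mix.sum()
            else:
                counts_cols[sid] = np.zeros(len(all_taxa), dtype=np.int64)
                mixture_cols[sid] = ctrl_mix
            samples.append(sid)
            metadata_rows.append({
                "sample_id": sid, "role": "negative_control", "replicate": rep,
                "treatment": "none", "timepoint_h": 0, "infection": infection,
                "species": "none",
            })
            truth_rows.append({
                "sample_id": sid, "biomass": 0.0, "w": 0.0, "depth": depth,
            })

    table = FeatureTable(pd.DataFrame(
        {s: counts_cols[s] for s in samples}, index=all_taxa
    ))
    metadata = SampleMetadata(
        pd.DataFrame(metadata_rows).set_index("sample_id")
    )
    origin = pd.Series(
        ["community"] * len(community_taxa) + ["contaminant"] * len(pool_taxa),
        index=all_taxa, name="origin",
    )
    truth = SyntheticTruth(
        taxon_origin=origin,
        sample_truth=pd.DataFrame(truth_rows).set_index("sample_id"),
        mixtures=pd.DataFrame({s: mixture_cols[s] for s in samples}, index=all_taxa),
        contaminant_pool=pd.Series(q, index=pool_taxa, name="pool"),
        planted_effects=tuple(config.planted_effects),
    )
    return table, metadata, taxonomy, truth


def generate_survival(hazards: dict, n_per_group: int, horizon_days: int,
                      seed: int) -> pd.DataFrame:
    """Simulate grouped survival records with daily monitoring.

    ``hazards`` maps group label to a constant daily hazard (> 0). Event
    times are exponential, discretised to whole days by ceiling (deaths are
    noticed at the next daily check) and administratively censored at
    ``horizon_days``.
    """
    if horizon_days < 1:
        raise ValidationError("censoring horizon before the first possible "
                              "event time: every record would be censored")
    for g, h in hazards.items():
        if h <= 0:
            raise ValidationError(f"non-positive hazard for group {g!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for g, h in hazards.items():
        t = np.ceil(rng.exponential(1.0 / h, size=n_per_group)).astype(int)
        event = t <= horizon_days
        t = np.minimum(t, horizon_days)
        for ti, ei in zip(t, event):
            rows.append({"time": int(ti), "event": int(ei), "group": g})
    return pd.DataFrame(rows)
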