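"""Synthetic soil-microbiome survey and multi-study generator with planted,
recoverable structure.

One latent soil-health axis h ~ Uniform(0, 100) per sample drives everything:

* the twelve CASH ratings are monotone noisy transforms of h — biological
  ratings and aggregate stability load positively, the (inverted) hardness
  ratings load negatively, chemical ratings mildly negatively, matching the
  qualitative correlation structure of field surveys;
* a planted fraction of OTUs responds to health: expected log relative
  abundance = baseline + direction * beta_scale * z(h) + noise, and counts
  are drawn multinomially at Poisson-distributed depth (the simplest model
  that induces compositionality);
* genus-level genomic traits are coupled to the planted direction: with
  trait_coupling near 1, genera of health-positive OTUs get smaller genomes
  and higher coding density, so community-weighted genome size falls with
  health;
* an external multi-study collection ("agro-ecosystem database" emulator)
  reuses the survey's ASV sequences for a configurable overlap fraction and
  plants two-level factor responses (till/no-till etc.) aligned with each
  OTU's health direction.

All randomness flows from the single ``seed`` through one named generator;
outputs are byte-identical across reruns with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import (
    Lineage,
    OtuTable,
    RANKS,
    RATING_NAMES,
    RatingsTable,
    UNCLASSIFIED,
)

#: loading of each rating on the latent health axis
RATING_LOADINGS: dict[str, float] = {
    "organic_matter": 0.90,
    "respiration": 0.85,
    "ace_protein": 0.85,
    "active_carbon": 0.90,
    "ph": -0.40,
    "phosphorus": -0.40,
    "potassium": -0.35,
    "minor_elements": -0.30,
    "aggregate_stability": 0.80,
    "available_water_capacity": 0.50,
    "surface_hardness": -0.80,
    "subsurface_hardness": -0.75,
}

#: registry of two-level study factors: factor -> (health-positive level,
#: health-negative level)
STUDY_FACTORS: dict[str, tuple[str, str]] = {
    "tillage": ("no_till", "till"),
    "water_regime": ("watered", "drought"),
    "om_management": ("om_amended", "unamended"),
    "fertilization": ("organic_fertilizer", "inorganic_fertilizer"),
}

SEQ_LEN = 100


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic survey and multi-study emulator."""

    n_samples: int = 200
    n_otus: int = 500
    depth_mean: float = 5000.0
    n_genera: int = 60
    n_families: int = 20
    n_orders: int = 8
    frac_planted_positive: float = 0.1
    frac_planted_negative: float = 0.1
    beta_scale: float = 1.2
    trait_coupling: float = 0.9
    noise_sd: float = 0.5
    baseline_sd: float = 1.0
    rating_noise_sd: float = 8.0
    frac_genus_unclassified: float = 0.2
    # multi-study emulator
    n_studies: int = 10
    samples_per_study: int = 20
    n_study_otus: int = 300
    overlap_fraction: float = 0.8
    n_planted_per_study: int = 20
    shift_factor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        fp, fn = self.frac_planted_positive, self.frac_planted_negative
        if not (0 <= fp <= 1 and 0 <= fn <= 1 and fp + fn <= 1):
            raise ConfigError("planted fractions must lie in [0,1] and sum to <= 1")
        for name in ("n_samples", "n_otus", "n_genera", "n_families", "n_orders",
                     "n_studies", "samples_per_study", "n_study_otus"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.depth_mean < 100:
            raise ConfigError("depth_mean must be >= 100")
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigError("overlap_fraction must lie in [0,1]")
        if not -1 <= self.trait_coupling <= 1:
            raise ConfigError("trait_coupling must lie in [-1,1]")
        if self.samples_per_study < 15:
            raise ConfigError("samples_per_study must be >= 15")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    latent_health: pd.Series  # sample -> h in (0, 100)
    direction: pd.Series  # otu -> {-1, 0, +1} response to health
    per_rating_direction: pd.DataFrame  # otu x rating expected correlation sign
    genus_traits: pd.DataFrame  # genus -> true mean trait vector
    study_effects: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def planted_otus(self) -> list[str]:
        return list(self.direction[self.direction != 0].index)


@dataclass
class SurveyData:
    """Bundle of all survey-scale synthetic inputs."""

    otus: OtuTable
    taxonomy: dict[str, Lineage]
    ratings: RatingsTable
    genomes: pd.DataFrame  # per-genome trait records with rank columns
    truth: GroundTruth


@dataclass
class AgroStudy:
    """One emulated external study: counts, its two-level factor, labels."""

    study_id: str
    otus: OtuTable
    factor: str
    labels: pd.Series  # sample -> level
    planted: dict[str, str]  # otu -> level in which it is enriched


def _make_seq(index: int, rng: np.random.Generator, length: int = SEQ_LEN) -> str:
    """Deterministic unique ASV sequence: 14-nt base-4 index prefix + random
    tail (uniqueness is guaranteed by the prefix)."""
    bases = "ACGT"
    prefix = []
    x = index
    for _ in range(14):
        prefix.append(bases[x % 4])
        x //= 4
    tail = rng.integers(0, 4, size=length - 14)
    return "".join(prefix) + "".join(bases[i] for i in tail)


def _balanced_taxonomy(cfg: SimConfig, rng: np.random.Generator):
    """Random balanced tree: genera nested in families nested in orders;
    a configurable fraction of OTUs left UNCLASSIFIED at genus."""
    genus_family = rng.integers(0, cfg.n_families, size=cfg.n_genera)
    family_order = rng.integers(0, cfg.n_orders, size=cfg.n_families)
    otu_genus = rng.integers(0, cfg.n_genera, size=cfg.n_otus)
    unclassified = rng.random(cfg.n_otus) < cfg.frac_genus_unclassified
    lineages: dict[str, Lineage] = {}
    for i in range(cfg.n_otus):
        g = otu_genus[i]
        f = genus_family[g]
        o = family_order[f]
        ranks = [
            "Bacteria",
            f"Phylum_{o % 4}",
            f"Class_{o % 6}",
            f"Order_{o}",
            f"Family_{f}",
            UNCLASSIFIED if unclassified[i] else f"Genus_{g}",
            UNCLASSIFIED,
        ]
        lineages[f"OTU_{i:04d}"] = Lineage(tuple(ranks))
    return otu_genus, genus_family, family_order, lineages


def _genus_trait_table(
    cfg: SimConfig,
    rng: np.random.Generator,
    otu_genus: np.ndarray,
    genus_family: np.ndarray,
    family_order: np.ndarray,
    direction: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True genus trait means coupled to planted direction, plus a per-genome
    record table (1-3 genomes per genus) around those means."""
    dbar = np.zeros(cfg.n_genera)
    for g in range(cfg.n_genera):
        member = otu_genus == g
        if member.any():
            dbar[g] = direction[member].mean()
    sd = dbar.std()
    dbar_std = dbar / sd if sd > 0 else dbar
    tc = cfg.trait_coupling
    latent = tc * dbar_std + np.sqrt(max(0.0, 1 - tc**2)) * rng.normal(size=cfg.n_genera)
    # health-positive genera (latent > 0): smaller genomes, denser coding,
    # fewer rrn copies -- the oligotroph end of the life-history spectrum
    size_mb = np.clip(4.0 - 1.2 * latent + rng.normal(0, 0.2, cfg.n_genera), 1.2, 9.0)
    coding = np.clip(0.97 - 0.016 * size_mb + rng.normal(0, 0.005, cfg.n_genera), 0.70, 0.99)
    rrn = np.clip(np.round(2.5 - 1.2 * latent + rng.normal(0, 0.4, cfg.n_genera)), 1, 12)
    crispr = np.clip(np.round(0.6 * size_mb + rng.normal(0, 0.5, cfg.n_genera)), 0, 15)
    bgc = np.clip(np.round(1.5 * size_mb + rng.normal(0, 1.0, cfg.n_genera)), 0, 40)
    genus_traits = pd.DataFrame(
        {
            "genome_size": size_mb * 1e6,
            "coding_density": coding,
            "rrn_copies": rrn,
            "crispr_arrays": crispr,
            "bgc_count": bgc,
            "planted_direction_mean": dbar,
        },
        index=[f"Genus_{g}" for g in range(cfg.n_genera)],
    )
    rows = []
    genome_i = 0
    for g in range(cfg.n_genera):
        f = genus_family[g]
        o = family_order[f]
        for _ in range(int(rng.integers(1, 4))):
            rows.append(
                {
                    "genome_id": f"GEN_{genome_i:05d}",
                    "domain": "Bacteria",
                    "phylum": f"Phylum_{o % 4}",
                    "class": f"Class_{o % 6}",
                    "order": f"Order_{o}",
                    "family": f"Family_{f}",
                    "genus": f"Genus_{g}",
                    "species": UNCLASSIFIED,
                    "genome_size": max(5e5, size_mb[g] * 1e6 + rng.normal(0, 1.5e5)),
                    "coding_density": float(np.clip(coding[g] + rng.normal(0, 0.004), 0.6, 0.999)),
                    "rrn_copies": float(max(1, rrn[g] + rng.integers(-1, 2))),
                    "crispr_arrays": float(max(0, crispr[g] + rng.integers(-1, 2))),
                    "bgc_count": float(max(0, bgc[g] + rng.integers(-2, 3))),
                }
            )
            genome_i += 1
    return genus_traits, pd.DataFrame(rows)


def simulate_survey(cfg: SimConfig) -> SurveyData:
    """Generate the survey-scale inputs: counts, taxonomy, ratings, genome
    records and the planted ground truth. Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    otu_ids = [f"OTU_{i:04d}" for i in range(cfg.n_otus)]

    h = rng.uniform(0, 100, size=cfg.n_samples)
    z = (h - h.mean()) / h.std()

    # ratings: monotone noisy transforms of h, clipped to the 0-100 scale
    ratings = {}
    for name in RATING_NAMES:
        loading = RATING_LOADINGS[name]
        raw = 50 + loading * (h - 50) + rng.normal(0, cfg.rating_noise_sd, cfg.n_samples)
        ratings[name] = np.clip(raw, 0, 100)
    dna_yield = np.clip(10 + 0.15 * (h - 50) + rng.normal(0, 3, cfg.n_samples), 0.1, None)
    p_no_till = 1 / (1 + np.exp(-(h - 50) / 15))
    tillage = np.where(rng.random(cfg.n_samples) < p_no_till, "no_till", "till")
    ratings_table = RatingsTable(
        pd.DataFrame(ratings, index=sample_ids),
        covariates=pd.DataFrame({"dna_yield": dna_yield}, index=sample_ids),
        tillage=pd.Series(tillage, index=sample_ids),
    )

    # planted directions
    n_pos = round(cfg.frac_planted_positive * cfg.n_otus)
    n_neg = round(cfg.frac_planted_negative * cfg.n_otus)
    planted_idx = rng.choice(cfg.n_otus, size=n_pos + n_neg, replace=False)
    direction = np.zeros(cfg.n_otus, dtype=int)
    direction[planted_idx[:n_pos]] = 1
    direction[planted_idx[n_pos:]] = -1

    baseline = rng.normal(0, cfg.baseline_sd, size=cfg.n_otus)
    log_abund = (
        baseline[None, :]
        + direction[None, :] * cfg.beta_scale * z[:, None]
        + rng.normal(0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_otus))
    )
    probs = np.exp(log_abund - log_abund.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    depths = rng.poisson(cfg.depth_mean, size=cfg.n_samples)
    depths = np.maximum(depths, 1)
    counts = np.vstack(
        [rng.multinomial(depths[s], probs[s]) for s in range(cfg.n_samples)]
    )

    sequences = {otu_ids[i]: _make_seq(i, rng) for i in range(cfg.n_otus)}
    otus = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids), sequences=sequences
    )

    otu_genus, genus_family, family_order, lineages = _balanced_taxonomy(cfg, rng)
    genus_traits, genomes = _genus_trait_table(
        cfg, rng, otu_genus, genus_family, family_order, direction
    )

    per_rating = pd.DataFrame(
        {
            name: direction * int(np.sign(RATING_LOADINGS[name]))
            for name in RATING_NAMES
        },
        index=otu_ids,
    )
    truth = GroundTruth(
        latent_health=pd.Series(h, index=sample_ids, name="latent_health"),
        direction=pd.Series(direction, index=otu_ids, name="direction"),
        per_rating_direction=per_rating,
        genus_traits=genus_traits,
    )
    return SurveyData(
        otus=otus, taxonomy=lineages, ratings=ratings_table, genomes=genomes, truth=truth
    )


def simulate_agroeco(cfg: SimConfig, survey: SurveyData) -> list[AgroStudy]:
    """Emulate a multi-study collection sharing ASV sequences with the survey.

    Each study gets >= 15 samples split evenly over one two-level factor from
    the registry. Planted indicator OTUs (drawn from the survey's planted
    OTUs where the overlap allows) receive a multiplicative abundance shift in
    the level matching their health direction: health-positive OTUs are
    enriched in the factor's health-positive level. Effects are recorded in
    ``survey.truth.study_effects``.
    """
    if survey.otus.sequences is None:
        raise ConfigError("survey OtuTable must carry sequences")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9151]))
    factors = list(STUDY_FACTORS)
    survey_ids = np.asarray(survey.otus.otu_ids)
    direction = survey.truth.direction
    studies: list[AgroStudy] = []
    new_seq_counter = 0
    for k in range(cfg.n_studies):
        study_id = f"STUDY_{k:03d}"
        factor = factors[k % len(factors)]
        pos_level, neg_level = STUDY_FACTORS[factor]

        n_overlap = round(cfg.overlap_fraction * cfg.n_study_otus)
        n_new = cfg.n_study_otus - n_overlap
        overlap = rng.choice(survey_ids, size=min(n_overlap, len(survey_ids)),
                             replace=False)
        otu_ids = list(overlap) + [
            f"{study_id}_OTU_{j:04d}" for j in range(n_new)
        ]
        seqs = {o: survey.otus.sequences[o] for o in overlap}
        for j in range(n_new):
            # index offset keeps study-local sequences distinct from survey's
            seqs[f"{study_id}_OTU_{j:04d}"] = _make_seq(
                10**6 + 10**4 * k + new_seq_counter + j, rng
            )
        new_seq_counter += n_new

        # planted indicators: prefer overlapped survey-planted OTUs so the
        # EWAS joins back onto the survey
        overlap_planted = [o for o in overlap if direction.get(o, 0) != 0]
        rng.shuffle(overlap_planted)
        chosen = overlap_planted[: cfg.n_planted_per_study]
        if len(chosen) < cfg.n_planted_per_study:
            pool = [o for o in otu_ids if o not in set(chosen)]
            extra = rng.choice(pool, size=cfg.n_planted_per_study - len(chosen),
                               replace=False)
            chosen = chosen + list(extra)
        planted: dict[str, str] = {}
        for o in chosen:
            d = direction.get(o, 0)
            if d == 0:
                d = int(rng.choice([-1, 1]))
            planted[o] = pos_level if d > 0 else neg_level

        n = cfg.samples_per_study
        n_a = n // 2
        labels = np.array([pos_level] * n_a + [neg_level] * (n - n_a))
        sample_ids = [f"{study_id}_S{j:03d}" for j in range(n)]
        baseline = rng.normal(0, cfg.baseline_sd, size=len(otu_ids))
        log_abund = baseline[None, :] + rng.normal(0, 0.3, size=(n, len(otu_ids)))
        log_shift = np.log(cfg.shift_factor)
        for j, o in enumerate(otu_ids):
            if o in planted:
                affected = labels == planted[o]
                log_abund[affected, j] += log_shift
        probs = np.exp(log_abund - log_abund.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        depths = np.maximum(rng.poisson(cfg.depth_mean, size=n), 1)
        counts = np.vstack([rng.multinomial(depths[s], probs[s]) for s in range(n)])
        table = OtuTable(
            pd.DataFrame(counts, index=sample_ids, columns=otu_ids), sequences=seqs
        )
        for o, level in planted.items():
            survey.truth.study_effects[(study_id, o)] = level
        studies.append(
            AgroStudy(
                study_id=study_id,
                otus=table,
                factor=factor,
                labels=pd.Series(labels, index=sample_ids, name=factor),
                planted=planted,
            )
        )
    return studies
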