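"""Environment-wide association survey (EWAS) of OTUs across many studies.

Each external study contributes a two-level factor (till vs. no-till, drought
vs. watered, ...). Indicator-species analysis scores every OTU per study; a
sign map declares which level of each factor is assumed beneficial for soil
health, so a significant indicator of the beneficial level gets +stat and of
the detrimental level -stat. Signed values are averaged per OTU within factor
categories (management, disturbance, plant association, biome, other), joined
onto the survey by exact ASV sequence identity, and turned into community-
weighted per-sample profiles exactly like genomic traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .indval import indval_permutation_test
from .tables_io import OtuTable, ValidationError
from .traits import CommunityProfile, community_weighted

logger = logging.getLogger("soilhealth")

CATEGORIES = ("management", "disturbance", "plant_association", "biome", "other")


@dataclass
class SignMap:
    """(factor, level) -> sign in {+1, -1}, plus category labels per factor.

    Two-level factors only: each factor has exactly one +1 and one -1 level.
    """

    signs: dict[tuple[str, str], int]
    categories: dict[str, str]
    sub_categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        per_factor: dict[str, list[int]] = {}
        for (factor, _level), sign in self.signs.items():
            if sign not in (1, -1):
                raise ValidationError(f"sign must be +1/-1, got {sign}")
            per_factor.setdefault(factor, []).append(sign)
        for factor, signs in per_factor.items():
            if sorted(signs) != [-1, 1]:
                raise ValidationError(
                    f"factor {factor!r} needs exactly one +1 and one -1 level"
                )
            if factor not in self.categories:
                raise ValidationError(f"factor {factor!r} has no category")
        bad = set(self.categories.values()) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown categories {sorted(bad)}")

    @property
    def factors(self) -> list[str]:
        return sorted({f for f, _ in self.signs})

    def sign_of(self, factor: str, level: str) -> int:
        return self.signs[(factor, level)]

    def flipped(self) -> "SignMap":
        return SignMap(
            signs={k: -v for k, v in self.signs.items()},
            categories=dict(self.categories),
            sub_categories=dict(self.sub_categories),
        )

    @classmethod
    def from_yaml(cls, path) -> "SignMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        signs: dict[tuple[str, str], int] = {}
        categories: dict[str, str] = {}
        sub: dict[str, str] = {}
        for factor, spec in doc.items():
            categories[factor] = spec["category"]
            if "sub_category" in spec:
                sub[factor] = spec["sub_category"]
            signs[(factor, spec["positive"])] = 1
            signs[(factor, spec["negative"])] = -1
        return cls(signs=signs, categories=categories, sub_categories=sub)

    def to_yaml(self, path) -> None:
        doc: dict[str, dict] = {}
        for (factor, level), sign in self.signs.items():
            entry = doc.setdefault(factor, {"category": self.categories[factor]})
            if factor in self.sub_categories:
                entry["sub_category"] = self.sub_categories[factor]
            entry["positive" if sign == 1 else "negative"] = level
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


def default_sign_map() -> SignMap:
    """Sign conventions for the factors named in the source survey's text:
    reduced tillage and organic-matter management are health-positive;
    tillage and drought are health-negative."""
    signs = {
        ("tillage", "no_till"): 1,
        ("tillage", "till"): -1,
        ("water_regime", "watered"): 1,
        ("water_regime", "drought"): -1,
        ("om_management", "om_amended"): 1,
        ("om_management", "unamended"): -1,
        ("fertilization", "organic_fertilizer"): 1,
        ("fertilization", "inorganic_fertilizer"): -1,
    }
    categories = {
        "tillage": "disturbance",
        "water_regime": "disturbance",
        "om_management": "management",
        "fertilization": "management",
    }
    sub = {
        "tillage": "tillage",
        "water_regime": "drought",
        "om_management": "organic_matter",
        "fertilization": "fertilizer_type",
    }
    return SignMap(signs=signs, categories=categories, sub_categories=sub)


@dataclass
class EwasScoreTable:
    """OTU x grouping signed mean indicator values aggregated over studies."""

    records: pd.DataFrame  # otu_id, group, mean_signed_stat, n_studies
    grouping: str

    def __post_init__(self) -> None:
        if len(self.records):
            if (np.abs(self.records["mean_signed_stat"]) > 1 + 1e-12).any():
                raise ValidationError("|mean_signed_stat| must be <= 1")
            if (self.records["n_studies"] < 1).any():
                raise ValidationError("n_studies must be >= 1")

    def scores_for(self, group: str) -> pd.Series:
        sub = self.records[self.records["group"] == group]
        return pd.Series(
            sub["mean_signed_stat"].to_numpy(), index=sub["otu_id"], name=group
        )


def score_studies(
    studies: Sequence[tuple[str, OtuTable, str, pd.Series]],
    signmap: SignMap,
    alpha: float = 0.05,
    min_samples: int = 15,
    n_perm: int = 999,
    seed: int | None = None,
    variant: str = "indval_g",
) -> pd.DataFrame:
    """Run indicator analysis per study and sign the significant indicators.

    ``studies``: (study_id, OtuTable, factor name, per-sample level labels).
    Studies whose factor is absent from the sign map, or with fewer than
    ``min_samples`` samples, are skipped with a warning. Returns a tidy frame
    (study_id, otu_id, factor, level, stat, p_adj, signed_stat).
    """
    rng = np.random.default_rng(seed)
    out = []
    for study_id, table, factor, labels in studies:
        if factor not in signmap.categories:
            logger.warning("study %s: factor %r absent from sign map, skipped",
                           study_id, factor)
            continue
        if len(table.sample_ids) < min_samples:
            logger.warning("study %s: only %d samples (< %d), skipped",
                           study_id, len(table.sample_ids), min_samples)
            continue
        depths = table.depths
        abund = table.counts.div(depths.where(depths > 0), axis=0) * 1000.0
        res = indval_permutation_test(
            abund, labels, n_perm=n_perm,
            seed=int(rng.integers(2**31)), variant=variant,
        )
        rec = res.records[res.records["p_adj"] < alpha].copy()
        if rec.empty:
            continue
        rec["study_id"] = study_id
        rec["factor"] = factor
        rec["signed_stat"] = rec.apply(
            lambda r: r["stat"] * signmap.sign_of(factor, r["level"]), axis=1
        )
        out.append(rec[["study_id", "otu_id", "factor", "level",
                        "stat", "p_adj", "signed_stat"]])
    if not out:
        return pd.DataFrame(columns=["study_id", "otu_id", "factor", "level",
                                     "stat", "p_adj", "signed_stat"])
    return pd.concat(out, ignore_index=True)


def aggregate_ewas(
    records: pd.DataFrame, signmap: SignMap, grouping: str = "category"
) -> EwasScoreTable:
    """Mean signed indicator value per OTU per category (or sub-category),
    averaged across contributing studies."""
    if grouping not in ("category", "sub_category"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if records.empty:
        raise ValidationError("no study records to aggregate")
    rec = records.copy()
    if grouping == "category":
        rec["group"] = rec["factor"].map(signmap.categories)
    else:
        rec["group"] = rec["factor"].map(signmap.sub_categories)
    rec = rec.dropna(subset=["group"])
    agg = (
        rec.groupby(["otu_id", "group"])
        .agg(mean_signed_stat=("signed_stat", "mean"), n_studies=("study_id", "nunique"))
        .reset_index()
    )
    return EwasScoreTable(records=agg, grouping=grouping)


def match_otus_by_sequence(survey: OtuTable, study: OtuTable) -> dict[str, str]:
    """Exact-sequence (ASV identity) mapping study otu_id -> survey otu_id.

    Both tables must carry length-harmonized sequences; duplicates within a
    table violate the ASV (dereplicated) contract and raise.
    """
    if survey.sequences is None or study.sequences is None:
        raise ValidationError("both tables must carry ASV sequences")
    lengths = {len(s) for s in survey.sequences.values()} | {
        len(s) for s in study.sequences.values()
    }
    if len(lengths) > 1:
        bad = sorted(
            o for table in (survey, study)
            for o, s in (table.sequences or {}).items()
            if len(s) != min(lengths)
        )
        raise ValidationError(
            f"sequence lengths differ after harmonization: {lengths}; ids {bad[:10]}"
        )
    for name, table in (("survey", survey), ("study", study)):
        seqs = list(table.sequences.values())
        if len(seqs) != len(set(seqs)):
            raise ValidationError(f"duplicate sequences within {name} table")
    by_seq = {seq.upper(): otu for otu, seq in survey.sequences.items()}
    return {
        otu: by_seq[seq.upper()]
        for otu, seq in study.sequences.items()
        if seq.upper() in by_seq
    }


def community_weighted_ewas(
    survey_abund: pd.DataFrame,
    scores: EwasScoreTable,
    group: str,
) -> CommunityProfile:
    """Community-weighted mean of a category's signed EWAS score per sample;
    same contract as the genomic-trait CWM. OTUs scored in the external
    studies but absent from the survey are ignored here."""
    values = scores.scores_for(group)
    values = values[values.index.isin(survey_abund.columns)]
    return community_weighted(survey_abund, values, trait=group)
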