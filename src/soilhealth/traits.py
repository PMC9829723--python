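"""Genomic-trait inference for OTUs and community-weighted trait profiles.

A genome table (genome id, lineage, genome size, coding density, rrn copies,
CRISPR arrays, BGC count — the shape of an IMG-ER export) is aggregated into
per-taxon mean trait vectors at every rank. Each OTU is then assigned the
trait vector of its lowest classified taxon that has a database entry,
walking genus -> family -> order -> class -> phylum -> domain. Community-
weighted means (CWM) weight assigned OTUs' trait values by their relative
abundance, renormalized over the assigned OTUs.

Gene-count traits (CRISPR arrays, BGCs) can be normalized by genome size and
reported per Mb; rrn copy number and coding density are never size-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import Lineage, RANKS, UNCLASSIFIED, ValidationError, parse_lineage

logger = logging.getLogger("soilhealth")

TRAIT_NAMES = ("genome_size", "coding_density", "rrn_copies", "crispr_arrays", "bgc_count")

#: traits divided by genome size (per Mb) under size normalization
SIZE_NORMALIZED_TRAITS = ("crispr_arrays", "bgc_count")

#: rank order tried during OTU assignment, lowest first
ASSIGN_ORDER = ("genus", "family", "order", "class", "phylum", "domain")


@dataclass
class TraitDB:
    """Genome records plus a (rank, taxon) -> mean trait vector lookup."""

    genomes: pd.DataFrame  # per-genome trait values + one column per rank
    lookup: pd.DataFrame  # index (rank, taxon); trait columns + n_genomes
    size_normalized: bool

    def get(self, rank: str, taxon: str) -> pd.Series | None:
        try:
            return self.lookup.loc[(rank, taxon)]
        except KeyError:
            return None


@dataclass
class TraitAssignment:
    """otu_id -> (trait vector, assigned_rank, matched_taxon); unassigned OTUs
    are absent from ``table``."""

    table: pd.DataFrame  # index otu_id; trait columns + assigned_rank, matched_taxon
    unassigned: list[str]

    @property
    def assigned_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class CommunityProfile:
    """Per-sample community-weighted trait values with assignment coverage."""

    values: pd.Series  # index = sample ids; NaN where no assigned abundance
    coverage: pd.Series  # fraction of relative abundance carried by assigned OTUs
    trait: str


def read_genome_table(path, lineage_column: str = "lineage",
                      dialect: str = "plain_semicolon") -> pd.DataFrame:
    """CSV of genome records with a lineage string column; returns a frame
    with one column per rank plus the trait columns. Genomes whose lineage
    fails to parse are skipped with a log entry."""
    df = pd.read_csv(path)
    missing = {"genome_id", lineage_column, *TRAIT_NAMES} - set(df.columns)
    if missing:
        raise ValidationError(f"genome table missing columns {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        try:
            lin = parse_lineage(str(row[lineage_column]), dialect=dialect)
        except ValidationError as exc:
            logger.warning("skipping genome %s: %s", row["genome_id"], exc)
            continue
        rec = {"genome_id": row["genome_id"]}
        rec.update({rank: lin.name_at(rank) for rank in RANKS})
        rec.update({t: float(row[t]) for t in TRAIT_NAMES})
        rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_traits(
    genomes: pd.DataFrame,
    size_normalize: bool = True,
    genus_mean_rollup: bool = True,
) -> TraitDB:
    """Aggregate per-genome traits to per-taxon means at every rank.

    With ``size_normalize`` on, CRISPR-array and BGC counts are divided by
    genome size (reported per Mb) *before* averaging. Ranks above genus are
    aggregated from genus-level means (each genus weighted equally) by
    default, which damps the cultivation bias of heavily sequenced genera;
    ``genus_mean_rollup=False`` pools genomes directly instead.
    """
    need = {"genome_id", *RANKS, *TRAIT_NAMES}
    missing = need - set(genomes.columns)
    if missing:
        raise ValidationError(f"genome records missing columns {sorted(missing)}")
    g = genomes.copy()
    if (g["genome_size"] <= 0).any():
        raise ValidationError("genome_size must be positive")
    if (g["coding_density"] > 1).any() or (g["coding_density"] <= 0).any():
        raise ValidationError("coding_density must lie in (0, 1]")
    if size_normalize:
        mb = g["genome_size"] / 1e6
        for t in SIZE_NORMALIZED_TRAITS:
            g[t] = g[t] / mb

    trait_cols = list(TRAIT_NAMES)
    chunks = []
    for rank in RANKS:
        named = g[g[rank] != UNCLASSIFIED]
        if named.empty:
            continue
        if genus_mean_rollup and rank != "genus" and RANKS.index(rank) < RANKS.index("genus"):
            # roll up from genus means where the genus is classified;
            # genomes unclassified at genus contribute as singleton pseudo-genera
            key = named["genus"].where(
                named["genus"] != UNCLASSIFIED, "genome:" + named["genome_id"].astype(str)
            )
            genus_means = named.groupby([named[rank], key])[trait_cols].mean()
            agg = genus_means.groupby(level=0)[trait_cols].mean()
            n = named.groupby(rank)["genome_id"].nunique()
        else:
            agg = named.groupby(rank)[trait_cols].mean()
            n = named.groupby(rank)["genome_id"].nunique()
        agg["n_genomes"] = n
        agg.index = pd.MultiIndex.from_product([[rank], agg.index], names=["rank", "taxon"])
        chunks.append(agg)
    lookup = pd.concat(chunks)
    return TraitDB(genomes=g, lookup=lookup, size_normalized=size_normalize)


def assign_traits(taxonomy: Mapping[str, Lineage], db: TraitDB) -> TraitAssignment:
    """Assign each OTU the mean trait vector of its lowest classified taxon
    present in the database, walking up the ranks; UNASSIGNED when no rank
    matches."""
    rows = []
    unassigned: list[str] = []
    for otu, lin in taxonomy.items():
        hit = None
        for rank in ASSIGN_ORDER:
            name = lin.name_at(rank)
            if name == UNCLASSIFIED:
                continue
            vec = db.get(rank, name)
            if vec is not None:
                hit = (rank, name, vec)
                break
        if hit is None:
            unassigned.append(otu)
            continue
        rank, name, vec = hit
        rec = {t: vec[t] for t in TRAIT_NAMES}
        rec["assigned_rank"] = rank
        rec["matched_taxon"] = name
        rows.append(pd.Series(rec, name=otu))
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=[*TRAIT_NAMES, "assigned_rank", "matched_taxon"]
    )
    if unassigned:
        logger.info("assign_traits: %d OTUs unassigned", len(unassigned))
    return TraitAssignment(table=table, unassigned=unassigned)


def community_weighted(
    abund: pd.DataFrame,
    assignment: TraitAssignment | pd.Series,
    trait: str,
) -> CommunityProfile:
    """Community-weighted mean of one trait per sample.

    Weights are each assigned OTU's relative abundance renormalized over the
    assigned OTUs; coverage reports the un-renormalized fraction of abundance
    they carry. Samples with zero assigned abundance get a missing value.
    """
    if isinstance(assignment, TraitAssignment):
        values = assignment.table[trait].astype(float)
    else:
        values = assignment.astype(float)
    assigned = [o for o in abund.columns if o in values.index]
    totals = abund.sum(axis=1)
    if not assigned:
        logger.warning("community_weighted: no assigned OTUs present in table")
        nan = pd.Series(np.nan, index=abund.index)
        return CommunityProfile(values=nan, coverage=pd.Series(0.0, index=abund.index),
                                trait=trait)
    sub = abund[assigned]
    v = values.loc[assigned].to_numpy()
    weight_sum = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = (sub.to_numpy() @ v) / weight_sum.to_numpy()
    out = pd.Series(cwm, index=abund.index, name=trait)
    empty = weight_sum == 0
    if empty.any():
        logger.warning(
            "community_weighted: %d sample(s) with zero assigned abundance -> missing",
            int(empty.sum()),
        )
        out[empty] = np.nan
    coverage = weight_sum / totals
    return CommunityProfile(values=out, coverage=coverage, trait=trait)


def community_profiles(
    abund: pd.DataFrame, assignment: TraitAssignment
) -> pd.DataFrame:
    """All traits' community-weighted means as a samples x traits frame."""
    return pd.DataFrame(
        {t: community_weighted(abund, assignment, t).values for t in TRAIT_NAMES}
    )


def trait_correlation_matrices(
    profiles: pd.DataFrame, db: TraitDB
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson trait x trait correlations from (A) per-sample community-
    weighted values and (B) per-genome database values. Symmetric with unit
    diagonal; constant traits yield missing off-diagonals."""
    if len(profiles) < 3 or len(db.genomes) < 3:
        raise ValidationError("need >= 3 samples and >= 3 genomes")
    cols = [c for c in TRAIT_NAMES if c in profiles.columns]
    mat_a = profiles[cols].corr(method="pearson")
    mat_b = db.genomes[cols].corr(method="pearson")
    for m in (mat_a, mat_b):
        np.fill_diagonal(m.values, 1.0)
    return mat_a, mat_b
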