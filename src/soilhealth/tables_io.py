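"""Data model and I/O for OTU count tables, taxonomy, soil-health ratings and
genome-trait tables.

The canonical in-memory containers are thin dataclasses around pandas objects.
Internal orientation is always samples x OTUs; readers transpose on a flag so
that a single convention holds everywhere downstream.

Soil-health ratings follow the CASH (Comprehensive Assessment of Soil Health)
framework: twelve 0-100 ratings split into biological, chemical and physical
classes, plus a total score defined as their unweighted mean.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("soilhealth")

# --------------------------------------------------------------------------
# Registries
# --------------------------------------------------------------------------

#: sentinel for a taxonomic rank without a usable name
UNCLASSIFIED = "UNCLASSIFIED"

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: The twelve CASH ratings and their property class.
RATING_CLASSES: dict[str, str] = {
    "organic_matter": "biological",
    "respiration": "biological",
    "ace_protein": "biological",
    "active_carbon": "biological",
    "ph": "chemical",
    "phosphorus": "chemical",
    "potassium": "chemical",
    "minor_elements": "chemical",
    "aggregate_stability": "physical",
    "available_water_capacity": "physical",
    "surface_hardness": "physical",
    "subsurface_hardness": "physical",
}

RATING_NAMES: tuple[str, ...] = tuple(RATING_CLASSES)

HARDNESS_RATINGS = ("surface_hardness", "subsurface_hardness")

TILLAGE_LEVELS = ("till", "no_till")

#: Placeholder tokens that map to UNCLASSIFIED when parsing lineages. The
#: original classification pipeline's exact token list is a config surface;
#: this default covers the common Silva placeholders.
DEFAULT_PLACEHOLDER_TOKENS = frozenset(
    {
        "",
        "uncultured",
        "metagenome",
        "unidentified",
        "unknown",
        "uncultured bacterium",
        "uncultured organism",
        "uncultured soil bacterium",
    }
)


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad header...)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with optional ASV sequences."""

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx, cols = self.counts.index, self.counts.columns
        if idx.has_duplicates:
            raise FormatError(f"duplicate sample ids: {sorted(idx[idx.duplicated()])}")
        if cols.has_duplicates:
            raise FormatError(f"duplicate OTU ids: {sorted(cols[cols.duplicated()])}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.isfinite(values).all():
            raise ValidationError("counts must be finite")
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if np.any(values != np.round(values)):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.sequences is not None:
            self.sequences = {k: v.upper() for k, v in self.sequences.items()}
            lengths = {len(s) for s in self.sequences.values()}
            if any(n < 50 for n in lengths):
                raise ValidationError("ASV sequences must be at least 50 nt")
            if len(lengths) > 1:
                raise ValidationError(
                    f"ASV sequences must share one length, got {sorted(lengths)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        seqs = None
        if self.sequences is not None:
            seqs = {o: self.sequences[o] for o in otu_ids if o in self.sequences}
        return OtuTable(self.counts[list(otu_ids)].copy(), sequences=seqs)


@dataclass(frozen=True)
class Lineage:
    """Seven-rank taxonomic lineage with top-down UNCLASSIFIED propagation."""

    ranks: tuple[str, ...]
    source_string: str = ""

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValidationError("Lineage needs exactly 7 ranks")
        seen_unclassified = False
        for name in self.ranks:
            if name == UNCLASSIFIED:
                seen_unclassified = True
            elif seen_unclassified:
                raise ValidationError(
                    "named rank below an UNCLASSIFIED rank in " + repr(self.ranks)
                )
            elif not name or name != name.strip():
                raise ValidationError(f"rank names must be non-empty and trimmed: {name!r}")

    def name_at(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    @property
    def lowest_classified_rank(self) -> str | None:
        """Deepest rank with a usable name, or None if fully unclassified."""
        for rank, name in zip(reversed(RANKS), reversed(self.ranks)):
            if name != UNCLASSIFIED:
                return rank
        return None


@dataclass
class RatingsTable:
    """Per-sample CASH ratings (twelve 0-100 columns) plus covariates/tillage."""

    ratings: pd.DataFrame  # index = sample ids, columns = the 12 rating names
    covariates: pd.DataFrame | None = None
    tillage: pd.Series | None = None  # values in {"till", "no_till"} or NaN

    def __post_init__(self) -> None:
        missing = set(RATING_NAMES) - set(self.ratings.columns)
        if missing:
            raise ValidationError(f"missing rating columns: {sorted(missing)}")
        extra = set(self.ratings.columns) - set(RATING_NAMES)
        if extra:
            raise ValidationError(f"unknown rating columns: {sorted(extra)}")
        self.ratings = self.ratings[list(RATING_NAMES)].astype(float)
        vals = self.ratings.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 100)
        if np.nansum(bad):
            raise ValidationError("ratings must lie in [0, 100]")
        if self.tillage is not None:
            labels = set(self.tillage.dropna().unique())
            if not labels <= set(TILLAGE_LEVELS):
                raise ValidationError(
                    f"tillage labels must be in {TILLAGE_LEVELS}, got {sorted(labels)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratings.index)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_otu_table(
    path,
    format: str = "tsv",
    samples_as_rows: bool = True,
    sequences: Mapping[str, str] | None = None,
) -> OtuTable:
    """Read a count table from TSV (header row + id column) or BIOM-style JSON.

    ``samples_as_rows`` declares the file's orientation; the returned table is
    always samples x OTUs.
    """
    if format == "tsv":
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header[1:]) != len(set(header[1:])):
                raise FormatError(f"duplicate column identifiers in {path}")
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if df.index.has_duplicates:
            raise FormatError(f"duplicate row identifiers in {path}")
        if not samples_as_rows:
            df = df.T
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric counts in {path}: {exc}") from exc
        return OtuTable(df, sequences=dict(sequences) if sequences else None)
    if format == "biom":
        with _open_text(path) as fh:
            doc = json.load(fh)
        sample_ids = [r["id"] for r in doc["columns"]]
        otu_ids = [r["id"] for r in doc["rows"]]
        mat = np.zeros((len(otu_ids), len(sample_ids)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        # BIOM convention: rows are observations (OTUs) -> transpose
        df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
        seqs = {
            r["id"]: r["metadata"]["sequence"]
            for r in doc["rows"]
            if r.get("metadata") and "sequence" in r["metadata"]
        } or None
        if sequences:
            seqs = dict(sequences)
        return OtuTable(df, sequences=seqs)
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        with _open_text(path, "wt") as fh:
            table.counts.to_csv(fh, sep="\t")
        return
    if format == "biom":
        rows = []
        for o in table.otu_ids:
            meta = None
            if table.sequences and o in table.sequences:
                meta = {"sequence": table.sequences[o]}
            rows.append({"id": o, "metadata": meta})
        mat = table.counts.to_numpy().T  # observations x samples
        data = [
            [int(i), int(j), float(mat[i, j])]
            for i, j in zip(*np.nonzero(mat))
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "shape": [len(table.otu_ids), len(table.sample_ids)],
            "rows": rows,
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with _open_text(path, "wt") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r}")


def parse_lineage(
    annotation: str,
    dialect: str = "silva_prefixed",
    placeholder_tokens: frozenset[str] = DEFAULT_PLACEHOLDER_TOKENS,
) -> Lineage:
    """Parse a semicolon-delimited lineage string into a 7-rank Lineage.

    ``silva_prefixed`` strips Silva-style rank prefixes (``d__``, ``p__``...).
    Placeholder tokens (empty, "uncultured", "metagenome", prefix-only fields)
    become UNCLASSIFIED; once a rank is unclassified all lower ranks are too.
    Candidate-clade labels (e.g. "KD4-96") are kept as valid names.
    """
    if not annotation or not annotation.strip():
        raise ValidationError("empty lineage annotation")
    fields = [f.strip() for f in annotation.split(";")]
    names: list[str] = []
    for tok in fields[:7]:
        if dialect == "silva_prefixed" and len(tok) >= 3 and tok[1:3] == "__":
            tok = tok[3:].strip()
        tok = tok.strip()
        if tok.lower() in placeholder_tokens:
            names.append(UNCLASSIFIED)
        else:
            names.append(tok)
    names.extend([UNCLASSIFIED] * (7 - len(names)))
    # top-down propagation: first unclassified rank truncates the rest
    out: list[str] = []
    truncated = False
    for name in names:
        if truncated or name == UNCLASSIFIED:
            truncated = True
            out.append(UNCLASSIFIED)
        else:
            out.append(name)
    return Lineage(tuple(out), source_string=annotation)


def read_taxonomy(path, dialect: str = "silva_prefixed") -> dict[str, Lineage]:
    """Two-column TSV (otu_id, lineage string) -> otu_id -> Lineage."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("taxonomy TSV needs two columns: otu_id, lineage")
    return {
        str(row.iloc[0]): parse_lineage(str(row.iloc[1]), dialect=dialect)
        for _, row in df.iterrows()
    }


def write_taxonomy(taxonomy: Mapping[str, Lineage], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lin in taxonomy.items():
            s = lin.source_string or ";".join(lin.ranks)
            fh.write(f"{otu}\t{s}\n")


def read_ratings(path) -> RatingsTable:
    """CSV with sample id column, twelve rating columns, optional covariates
    and a ``tillage`` column."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, index_col=0)
    ratings = df[[c for c in df.columns if c in RATING_CLASSES]]
    tillage = None
    if "tillage" in df.columns:
        tillage = df["tillage"].where(df["tillage"].isin(TILLAGE_LEVELS))
    cov_cols = [c for c in df.columns if c not in RATING_CLASSES and c != "tillage"]
    covariates = df[cov_cols].apply(pd.to_numeric) if cov_cols else None
    return RatingsTable(ratings, covariates=covariates, tillage=tillage)


def write_ratings(table: RatingsTable, path) -> None:
    df = table.ratings.copy()
    if table.covariates is not None:
        df = df.join(table.covariates)
    if table.tillage is not None:
        df["tillage"] = table.tillage
    with _open_text(path, "wt") as fh:
        df.to_csv(fh)


# --------------------------------------------------------------------------
# Rating utilities
# --------------------------------------------------------------------------


def invert_hardness(table: RatingsTable) -> RatingsTable:
    """Flip surface/sub-surface hardness ratings to 100 - x so that more
    compacted soils get *higher* ratings. Missing values stay missing; the
    operation is an involution."""
    ratings = table.ratings.copy()
    for col in HARDNESS_RATINGS:
        ratings[col] = 100.0 - ratings[col]
    return RatingsTable(ratings, covariates=table.covariates, tillage=table.tillage)


def total_health_score(table: RatingsTable) -> pd.Series:
    """Unweighted mean of the twelve ratings; NaN when any rating is missing."""
    r = table.ratings
    score = r.mean(axis=1)
    score[r.isna().any(axis=1)] = np.nan
    score.name = "total_health_score"
    return score
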