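"""Genus-level co-occurrence networks of shared bioindicator status.

Bioindicator OTUs are aggregated to their lowest resolved taxonomic rank
(usually genus). Two taxa are connected when they contain OTUs indicating at
least one common health rating in the requested direction; the edge weight
counts the unordered OTU pairs that co-indicate. Positive- and negative-
direction graphs are built separately. Nodes carry the number of member
indicator OTUs, a majority-rule health-class label (biological / chemical /
physical, hyphenated on ties) and a described-species flag. Graphs export to
Gephi-readable GEXF or GraphML via networkx.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from typing import Mapping

import networkx as nx

from .bioindicators import BioindicatorSet
from .tables_io import Lineage, RATING_CLASSES, UNCLASSIFIED

logger = logging.getLogger("soilhealth")

#: fixed order used to build hyphenated tie labels
CLASS_ORDER = ("biological", "chemical", "physical")

#: tokens marking a candidate-clade / non-described genus label
CANDIDATE_PATTERNS = (
    re.compile(r"^Candidatus\b", re.IGNORECASE),
    re.compile(r"^Ca\.", re.IGNORECASE),
    re.compile(r"\d"),  # alphanumeric placeholder clades like KD4-96, RB41
    re.compile(r"^uncultured", re.IGNORECASE),
)


def node_label(lineage: Lineage) -> str:
    """Lowest resolved taxon name, or UNCLASSIFIED for fully unresolved."""
    rank = lineage.lowest_classified_rank
    if rank is None:
        return UNCLASSIFIED
    return lineage.name_at(rank)


def is_described_species(label: str, extra_candidate_tokens: tuple[str, ...] = ()) -> bool:
    """True when a node label looks like a validly described genus rather
    than a candidate clade or placeholder."""
    if label == UNCLASSIFIED:
        return False
    if label in extra_candidate_tokens:
        return False
    return not any(p.search(label) for p in CANDIDATE_PATTERNS)


def majority_class(ratings: list[str]) -> str:
    """Majority-rule health-class label for a node's indicated ratings.

    Each indicated rating votes for its class; a strict majority wins,
    otherwise the tied top classes are hyphenated in fixed class order.
    """
    votes = Counter(RATING_CLASSES[r] for r in ratings)
    top = max(votes.values())
    winners = [c for c in CLASS_ORDER if votes.get(c, 0) == top]
    return "-".join(winners)


def build_network(
    bset: BioindicatorSet,
    taxonomy: Mapping[str, Lineage],
    direction: int,
) -> nx.Graph:
    """Co-occurrence graph of taxa sharing bioindicator status in one
    direction (+1 or -1).

    Edge weight between taxa u != v = number of unordered OTU pairs
    (one from each taxon) sharing at least one common indicated rating in
    the requested direction. Within-taxon co-indication is recorded as the
    node attribute ``n_within_pairs`` instead of a self-loop.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    rec = bset.records[bset.records["direction"] == direction]
    g = nx.Graph(direction="positive" if direction == 1 else "negative")
    if rec.empty:
        logger.warning("build_network: no indicators with direction %+d", direction)
        return g

    # otu -> (taxon label, set of indicated ratings)
    otu_ratings: dict[str, set[str]] = {}
    otu_taxon: dict[str, str] = {}
    for otu, sub in rec.groupby("otu_id"):
        otu_ratings[otu] = set(sub["rating"])
        otu_taxon[otu] = node_label(taxonomy[otu])

    taxa: dict[str, list[str]] = {}
    for otu, taxon in otu_taxon.items():
        taxa.setdefault(taxon, []).append(otu)

    for taxon, otus in taxa.items():
        all_ratings = [r for o in otus for r in otu_ratings[o]]
        within = sum(
            1
            for i in range(len(otus))
            for j in range(i + 1, len(otus))
            if otu_ratings[otus[i]] & otu_ratings[otus[j]]
        )
        g.add_node(
            taxon,
            n_otus=len(otus),
            class_label=majority_class(all_ratings),
            described_species=is_described_species(taxon),
            n_within_pairs=within,
        )

    labels = sorted(taxa)
    for i, u in enumerate(labels):
        for v in labels[i + 1 :]:
            weight = sum(
                1
                for ou in taxa[u]
                for ov in taxa[v]
                if otu_ratings[ou] & otu_ratings[ov]
            )
            if weight:
                g.add_edge(u, v, weight=weight)
    return g


def export_graph(graph: nx.Graph, path, format: str = "gexf") -> None:
    """Write a Gephi-readable GEXF 1.2 or GraphML file."""
    if format == "gexf":
        nx.write_gexf(graph, path)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graph(path, format: str = "gexf") -> nx.Graph:
    if format == "gexf":
        return nx.read_gexf(path)
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown format {format!r}")
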