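"""Multi-residence screening from average-nucleotide-identity (ANI) tables.

Whether the same strain or species occurs in several body sites matters
for interpreting inter-niche transfers: a genome pair from different
sites with >99.9% ANI is the same strain, >95% the same species.  This
module counts cross-site genome pairs, bins high-identity cross-site
pairs at the strain and species thresholds, screens genomes against a
contaminant-genus blacklist, and reduces multi-residence pairs to
connected species networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .genesets import GenomeMetadata

ANI_COLUMNS = ["query", "reference", "ani", "matched_fragments", "total_fragments"]


@dataclass(frozen=True)
class ANIRecord:
    query: str
    reference: str
    ani: float
    matched_fragments: int = 0
    total_fragments: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ani <= 100.0):
            raise ValueError(f"ANI {self.ani} outside [0, 100]")


def read_ani_tsv(path) -> list[ANIRecord]:
    """FastANI-style output: query, reference, ANI, matched fragments,
    total fragments (headerless, tab-separated)."""
    df = pd.read_csv(path, sep="\t", header=None, names=ANI_COLUMNS)
    return [
        ANIRecord(str(r.query), str(r.reference), float(r.ani),
                  int(r.matched_fragments), int(r.total_fragments))
        for r in df.itertuples()
    ]


def cross_site_pairs(meta: GenomeMetadata) -> tuple[list[tuple[str, str]], int]:
    """All unordered genome pairs residing in different body sites.

    The count satisfies count + sum over sites of C(n_site, 2) = C(N, 2).
    """
    genomes = meta.genome_ids
    pairs = [
        (a, b)
        for i, a in enumerate(genomes)
        for b in genomes[i + 1:]
        if meta.site_of(a) != meta.site_of(b)
    ]
    return pairs, len(pairs)


def _dedupe_max(records: Iterable[ANIRecord]) -> dict[tuple[str, str], float]:
    """Unordered pairs with the maximum identity of the two directions;
    self-comparisons dropped (they serve only as a positive control)."""
    best: dict[tuple[str, str], float] = {}
    for r in records:
        if r.query == r.reference:
            continue
        key = (min(r.query, r.reference), max(r.query, r.reference))
        if key not in best or r.ani > best[key]:
            best[key] = r.ani
    return best


def bin_residence(records: Iterable[ANIRecord], meta: GenomeMetadata,
                  strain_thr: float = 99.9, species_thr: float = 95.0,
                  same_genus_only: bool = True,
                  ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Cross-site pairs above the strain and species ANI thresholds.

    Pairs from the same body site are excluded (the question is
    multi-residence), as are different-genus pairs when
    ``same_genus_only`` (genomes of different genera cannot be one
    species).  Strain-level pairs are a subset of species-level pairs
    whenever strain_thr >= species_thr.
    """
    strain, species = [], []
    for (a, b), ani in sorted(_dedupe_max(records).items()):
        if meta.site_of(a) == meta.site_of(b):
            continue
        if same_genus_only and meta.genus_of(a) != meta.genus_of(b):
            continue
        if ani > species_thr:
            species.append((a, b))
        if ani > strain_thr:
            strain.append((a, b))
    return strain, species


def contaminant_screen(meta: GenomeMetadata,
                       blacklist: Sequence[str]) -> pd.DataFrame:
    """Per-site count and fraction of genomes whose genus is blacklisted."""
    black = set(blacklist)
    rows = []
    for site in meta.sites:
        genomes = [g for g in meta.genome_ids if meta.site_of(g) == site]
        hits = [g for g in genomes if meta.genus_of(g) in black]
        rows.append({
            "body_site": site,
            "n_genomes": len(genomes),
            "n_contaminant": len(hits),
            "fraction": len(hits) / len(genomes) if genomes else 0.0,
        })
    return pd.DataFrame(rows)


def residence_network(pairs: Iterable[tuple[str, str]],
                      meta: GenomeMetadata | None = None) -> nx.Graph:
    """Graph of multi-residence genome pairs; nodes annotated with body
    site when metadata is given."""
    g = nx.Graph()
    for a, b in pairs:
        g.add_edge(a, b)
    if meta is not None:
        for n in g.nodes:
            g.nodes[n]["body_site"] = meta.site_of(n)
    return g


def network_components(g: nx.Graph,
                       meta: GenomeMetadata | None = None) -> pd.DataFrame:
    """Connected components (species networks) with size and body-site
    composition, largest first."""
    rows = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        row = {"size": len(members), "members": ";".join(members)}
        if meta is not None:
            sites = sorted({meta.site_of(m) for m in members})
            row["sites"] = ";".join(sites)
            row["n_sites"] = len(sites)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["size", "members"],
                              ascending=[False, True]).reset_index(drop=True)
        out.insert(0, "component", [f"C{i+1}" for i in range(len(out))])
    return out


def export_network(g: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        df = pd.DataFrame(sorted(g.edges()), columns=["genome_a", "genome_b"])
        df.to_csv(edgelist_path, sep="\t", index=False)
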