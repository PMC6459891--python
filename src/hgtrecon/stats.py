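"""HGT summary statistics and gene-selection rules.

Two HGT indices quantify transfer participation: the *gene* HGT-index of
a family is the number of transfer events detected on its gene tree
divided by the family's taxon count; the *genome* HGT-index is the
fraction of a genome's genes that participate in at least one transfer
(the genome descends from a donor or recipient endpoint).  Per-family
HGT-ratios split events by cardinality class, and events are stratified
by phylogenetic similarity (same genus: PS, else PD) crossed with habitat
(same body site: SH, else DH).  Selection rules derive frequently
transferred genes (FTGs, top decile of the gene HGT-index), recently
transferred genes (RTGs, high one-to-one proportion after minimum-size
filters), widespread/core genes, and low-HGT phylogenetic marker
candidates.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CARDINALITIES, HGTEvent
from .genesets import GeneSet, GenomeMetadata


def gene_hgt_index(n_events: int, n_taxa: int) -> float:
    """Transfer events on a gene tree divided by its taxon count."""
    if n_taxa <= 0:
        raise ValueError("n_taxa must be positive")
    return n_events / n_taxa


def build_gene_profiles(events: Iterable[HGTEvent],
                        sets: Sequence[GeneSet],
                        meta: Optional[GenomeMetadata] = None) -> pd.DataFrame:
    """Per-family profile: taxon count, event counts per cardinality class,
    gene HGT-index, one-to-one ratio, genus count, Pfam id."""
    per_set: dict[str, dict[str, int]] = {}
    for ev in events:
        d = per_set.setdefault(ev.gene_set_id, {c: 0 for c in CARDINALITIES})
        d[ev.cardinality] += 1
    rows = []
    for gs in sets:
        counts = per_set.get(gs.set_id, {c: 0 for c in CARDINALITIES})
        n_events = sum(counts.values())
        row = {
            "gene_set_id": gs.set_id,
            "n_taxa": gs.n_taxa,
            "n_events": n_events,
            **counts,
            "hgt_index": gene_hgt_index(n_events, gs.n_taxa),
            "pfam": gs.pfam,
        }
        row["one_to_one_ratio"] = (counts["one_to_one"] / n_events) if n_events else np.nan
        if meta is not None:
            row["n_genera"] = len({meta.genus_of(g) for g in gs.genomes})
        rows.append(row)
    return pd.DataFrame(rows)


def hgt_ratio(profile: Mapping, cardinality: str) -> float:
    """Fraction of a family's events in one cardinality class; the three
    class ratios sum to 1.  Undefined (raises) for event-free families."""
    if cardinality not in CARDINALITIES:
        raise ValueError(f"unknown cardinality {cardinality!r}")
    total = int(profile["n_events"])
    if total == 0:
        raise ValueError("HGT-ratio undefined for a family with no events")
    return int(profile[cardinality]) / total


def genome_participation(events: Iterable[HGTEvent]) -> dict[str, set]:
    """genome id -> set of gene set ids in which the genome descends from
    a donor or recipient endpoint of at least one event."""
    out: dict[str, set] = {}
    for ev in events:
        for g in ev.donor | ev.recipient:
            out.setdefault(g, set()).add(ev.gene_set_id)
    return out


def genome_hgt_index(genome_id: str, events: Iterable[HGTEvent],
                     meta: GenomeMetadata) -> float:
    """Participating genes of the genome divided by its total gene count."""
    total = meta.n_genes_of(genome_id)
    part = genome_participation(events).get(genome_id, set())
    return len(part) / total


def build_genome_profiles(events: Iterable[HGTEvent],
                          meta: GenomeMetadata) -> pd.DataFrame:
    part = genome_participation(list(events))
    rows = []
    for g in meta.genome_ids:
        n_part = len(part.get(g, set()))
        total = meta.n_genes_of(g)
        rows.append({
            "genome_id": g,
            "body_site": meta.site_of(g),
            "n_hgt_genes": n_part,
            "n_genes": total,
            "hgt_index": n_part / total,
        })
    return pd.DataFrame(rows)


def stratify_event(ev: HGTEvent) -> tuple[str, str]:
    """(PS|PD, SH|DH): phylogenetically similar when all endpoint genomes
    share one genus; similar habitat when the event is intra-niche."""
    phylo = "PS" if len(ev.donor_genera | ev.recipient_genera) == 1 else "PD"
    habitat = "SH" if ev.niche == "intra" else "DH"
    return phylo, habitat


def strata_ratio_summary(events: Iterable[HGTEvent],
                         profiles: pd.DataFrame) -> pd.DataFrame:
    """Median per-family HGT-ratio for each cardinality class within each
    PS/PD x SH/DH stratum.  A family's events contribute its class ratios
    to every stratum one of its events falls in."""
    prof = profiles.set_index("gene_set_id")
    bucket: dict[tuple[str, str, str], list[float]] = {}
    seen: set[tuple[str, str, str]] = set()
    for ev in events:
        stratum = stratify_event(ev)
        for card in CARDINALITIES:
            key = (stratum[0], stratum[1], card)
            pair = (ev.gene_set_id, *stratum)
            row = prof.loc[ev.gene_set_id]
            if (pair[0], pair[1] + pair[2], card) in seen:
                continue
            seen.add((pair[0], pair[1] + pair[2], card))
            bucket.setdefault(key, []).append(
                hgt_ratio(row, card) if row["n_events"] else np.nan
            )
    rows = [
        {"phylo": k[0], "habitat": k[1], "cardinality": k[2],
         "median_ratio": float(np.median(v)), "n_families": len(v)}
        for k, v in sorted(bucket.items())
    ]
    return pd.DataFrame(rows, columns=["phylo", "habitat", "cardinality",
                                       "median_ratio", "n_families"])


def _pair_identity(sa: str, sb: str) -> float:
    comp = [(x, y) for x, y in zip(sa.upper(), sb.upper())
            if x not in "-." and y not in "-."]
    if not comp:
        raise ValueError("no comparable columns between sequences")
    return 100.0 * sum(x == y for x, y in comp) / len(comp)


def transfer_pair_identity(ev: HGTEvent, gs: GeneSet) -> float:
    """Mean percent identity over all (donor-descendant, recipient-
    descendant) sequence pairs of the family's alignment."""
    aln = gs.alignment()
    donors = sorted(ev.donor & set(gs.genomes))
    recips = sorted(ev.recipient & set(gs.genomes))
    missing = [g for g in itertools.chain(donors, recips) if g not in aln]
    if missing or not donors or not recips:
        raise ValueError(f"missing sequences for event endpoints in {gs.set_id}")
    vals = [_pair_identity(aln[d], aln[r]) for d in donors for r in recips]
    return float(np.mean(vals))


def _top_decile(values: pd.Series) -> pd.Index:
    """Indices of the top 10% by value (nearest-rank: floor(n/10) items,
    minimum one), with boundary ties included."""
    n = len(values)
    k = max(1, n // 10)
    ranked = values.sort_values(ascending=False, kind="mergesort")
    cutoff = ranked.iloc[k - 1]
    return values.index[values >= cutoff]


def select_ftg(profiles: pd.DataFrame) -> list[str]:
    """Frequently transferred genes: top decile of the gene HGT-index."""
    if len(profiles) < 10:
        raise ValueError("need at least 10 profiles to take a top decile")
    idx = _top_decile(profiles["hgt_index"])
    return sorted(profiles.loc[idx, "gene_set_id"])


def select_rtg(profiles: pd.DataFrame, min_events: int = 5, min_genera: int = 5,
               min_genomes: int = 10) -> pd.DataFrame:
    """Recently transferred genes: after removing families with <5 events,
    <5 genera, or <10 genomes, rank by one-to-one ratio (descending) and
    return the top decile (ties included), ranked."""
    if "n_genera" not in profiles.columns:
        raise ValueError("profiles need an n_genera column (pass meta when building)")
    ok = profiles[(profiles["n_events"] >= min_events)
                  & (profiles["n_genera"] >= min_genera)
                  & (profiles["n_taxa"] >= min_genomes)]
    if ok.empty:
        return ok.copy()
    idx = _top_decile(ok["one_to_one_ratio"])
    out = ok.loc[idx].sort_values(["one_to_one_ratio", "gene_set_id"],
                                  ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def presence_fraction(gs: GeneSet, genome_pool: Iterable[str]) -> float:
    pool = set(genome_pool)
    if not pool:
        raise ValueError("empty genome pool")
    return len(set(gs.genomes) & pool) / len(pool)


def widespread_genes(sets: Sequence[GeneSet], meta: GenomeMetadata,
                     sites: Iterable[str], frac: float = 0.7) -> list[str]:
    """Families present in strictly more than *frac* of the genomes of the
    queried body site(s) (a single site or a pooled combination)."""
    sites = list(sites)
    if not sites:
        raise ValueError("empty site set")
    unknown = set(sites) - set(meta.sites)
    if unknown:
        raise ValueError(f"unknown body site(s): {sorted(unknown)}")
    pool = [g for g in meta.genome_ids if meta.site_of(g) in set(sites)]
    return sorted(gs.set_id for gs in sets if presence_fraction(gs, pool) > frac)


def core_genes(sets: Sequence[GeneSet], meta: GenomeMetadata,
               frac: float = 0.7) -> list[str]:
    """Widespread over all genomes pooled."""
    return widespread_genes(sets, meta, meta.sites, frac=frac)


def marker_candidates(profiles: pd.DataFrame, sets: Sequence[GeneSet],
                      meta: GenomeMetadata, presence_frac: float = 0.9,
                      max_index: float = 0.2) -> list[str]:
    """Low-HGT marker candidates: presence in strictly more than
    *presence_frac* of all genomes and gene HGT-index strictly below
    *max_index*."""
    prof = profiles.set_index("gene_set_id")
    pool = meta.genome_ids
    out = []
    for gs in sets:
        if gs.set_id not in prof.index:
            continue
        if (presence_fraction(gs, pool) > presence_frac
                and prof.loc[gs.set_id, "hgt_index"] < max_index):
            out.append(gs.set_id)
    return sorted(out)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   test: str = "rank_sum") -> float:
    """Two-sided group comparison p-value: Mann-Whitney U ('rank_sum') or
    Welch's unequal-variance t-test ('welch_t')."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "rank_sum":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "welch_t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("degenerate groups (zero variance in both)")
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")
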