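"""Classification of transfers by cardinality and niche, and the per-site
and two-site bookkeeping tables.

A transfer is *one-to-one* when donor and recipient are both extant
genomes (species-tree leaves), *one-to-many* when exactly one endpoint is
ancestral (many-to-one is folded in), and *many-to-many* when both are.
It is *intra-niche* when every extant genome descending from either
endpoint occupies a single body site, *inter-niche* otherwise.  Endpoint
descendant sets are taken within the gene set's taxa (the species tree is
pruned to the family before reconciliation), i.e. the evidence scope of
the gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genesets import GenomeMetadata
from .reconcile import TransferRecord

CARDINALITIES = ("one_to_one", "one_to_many", "many_to_many")


@dataclass(frozen=True)
class HGTEvent:
    """One classified transfer."""

    gene_set_id: str
    gene_node: str
    donor: frozenset
    recipient: frozenset
    cardinality: str
    niche: str               # 'intra' | 'inter'
    sites: frozenset
    donor_genera: frozenset
    recipient_genera: frozenset
    scope: str               # gene-set scope: 'unique' | 'mixed'


def classify_cardinality(t: TransferRecord) -> str:
    """Cardinality class from the endpoint leaf sets."""
    donor_leaf = len(t.donor) == 1
    recip_leaf = len(t.recipient) == 1
    if donor_leaf and recip_leaf:
        return "one_to_one"
    if donor_leaf or recip_leaf:
        return "one_to_many"
    return "many_to_many"


def classify_niche(t: TransferRecord, meta: GenomeMetadata) -> tuple[str, frozenset]:
    """('intra'|'inter', involved body-site set).

    The site set is the union of body sites of extant genomes descending
    from the donor and from the recipient node.
    """
    sites = frozenset(meta.site_of(g) for g in (t.donor | t.recipient))
    return ("intra" if len(sites) == 1 else "inter"), sites


def annotate_transfer(t: TransferRecord, gene_set_id: str, scope: str,
                      meta: GenomeMetadata) -> HGTEvent:
    niche, sites = classify_niche(t, meta)
    return HGTEvent(
        gene_set_id=gene_set_id,
        gene_node=t.gene_node,
        donor=t.donor,
        recipient=t.recipient,
        cardinality=classify_cardinality(t),
        niche=niche,
        sites=sites,
        donor_genera=frozenset(meta.genus_of(g) for g in t.donor),
        recipient_genera=frozenset(meta.genus_of(g) for g in t.recipient),
        scope=scope,
    )


def complete_site_tally(df: pd.DataFrame) -> pd.DataFrame:
    """Fill the derived columns of a per-site tally: c = a + b and
    e = d / c (reported to 2 decimals; blank when c = 0).

    Columns a (intra events from unique sets), b (intra events from mixed
    sets) and d (inter events involving the site) must be present.
    """
    out = df.copy()
    out["c"] = out["a"] + out["b"]
    ratio = out["d"] / out["c"].where(out["c"] > 0)
    out["e"] = ratio.round(2)
    return out[["a", "b", "c", "d", "e"]]


def tally_by_site(events: Iterable[HGTEvent], sites: Sequence[str]) -> pd.DataFrame:
    """Per-body-site event bookkeeping.

    Intra-niche events count once for their single site, split by gene-set
    scope (column a: unique sets, b: mixed sets).  Inter-niche events
    count once for *every* site they involve (column d), so the d column
    sums to more than the number of inter events.
    """
    idx = list(sites)
    tab = pd.DataFrame(0, index=idx, columns=["a", "b", "d"], dtype=int)
    for ev in events:
        unknown = ev.sites - set(idx)
        if unknown:
            raise ValueError(f"unknown body site(s): {sorted(unknown)}")
        if ev.niche == "intra":
            (site,) = ev.sites
            tab.loc[site, "a" if ev.scope == "unique" else "b"] += 1
        else:
            for site in ev.sites:
                tab.loc[site, "d"] += 1
    out = complete_site_tally(tab)
    out.index.name = "body_site"
    return out


def two_site_tally(events: Iterable[HGTEvent],
                   set_sites: Mapping[str, frozenset]) -> pd.DataFrame:
    """Event counts for mixed gene sets spanning exactly two body sites.

    *set_sites* maps gene set id -> body-site set of its member genomes.
    Gene sets spanning one or more than two sites are excluded.  Rows are
    (site pair, total, intra, inter) with total = intra + inter, sorted by
    inter descending then pair name.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for ev in events:
        span = set_sites.get(ev.gene_set_id)
        if span is None or len(span) != 2:
            continue
        pair = tuple(sorted(span))
        bucket = rows.setdefault(pair, [0, 0])
        bucket[0 if ev.niche == "intra" else 1] += 1
    recs = [
        {"site_a": p[0], "site_b": p[1], "total": i + x, "intra": i, "inter": x}
        for p, (i, x) in rows.items()
    ]
    out = pd.DataFrame(recs, columns=["site_a", "site_b", "total", "intra", "inter"])
    if not out.empty:
        out = out.sort_values(["inter", "site_a", "site_b"],
                              ascending=[False, True, True]).reset_index(drop=True)
    return out


def events_to_frame(events: Iterable[HGTEvent]) -> pd.DataFrame:
    """Flat event table (one row per transfer) for TSV export."""
    rows = []
    for ev in events:
        rows.append({
            "gene_set_id": ev.gene_set_id,
            "gene_node": ev.gene_node,
            "donor": ";".join(sorted(ev.donor)),
            "recipient": ";".join(sorted(ev.recipient)),
            "cardinality": ev.cardinality,
            "niche": ev.niche,
            "sites": ";".join(sorted(ev.sites)),
            "donor_genera": ";".join(sorted(ev.donor_genera)),
            "recipient_genera": ";".join(sorted(ev.recipient_genera)),
            "scope": ev.scope,
        })
    return pd.DataFrame(rows, columns=[
        "gene_set_id", "gene_node", "donor", "recipient", "cardinality",
        "niche", "sites", "donor_genera", "recipient_genera", "scope",
    ])
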