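"""Model/Results interface orchestrating the HGT detection pipeline.

:class:`HGTAnalysis` is built from the data (a rooted species tree,
per-family unrooted gene trees, genome metadata); :meth:`HGTAnalysis.fit`
filters the families, reconciles each gene tree against the species tree
pruned to the family's taxa, classifies every transfer, and returns an
:class:`HGTResults` carrying the event table, per-gene and per-genome HGT
profiles, the bookkeeping tallies, and a text :meth:`~HGTResults.summary`.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .classify import (HGTEvent, annotate_transfer, events_to_frame,
                       tally_by_site, two_site_tally)
from .genesets import (GeneSet, GeneSetMember, GenomeMetadata, filter_gene_sets,
                       geneset_scope, zero_distance_filter)
from .reconcile import DTLCosts, Reconciliation, reconcile_unrooted
from .stats import (build_gene_profiles, build_genome_profiles, core_genes,
                    marker_candidates, select_ftg, select_rtg,
                    strata_ratio_summary, widespread_genes)
from .trees import binarize, leaf_labels, prune_to_taxa


class HGTAnalysis:
    """Phylogeny-based HGT detection on a set of gene families.

    Parameters
    ----------
    species_tree : rooted reference tree over all genomes.
    gene_trees : mapping family id -> unrooted gene tree whose leaves are
        genome ids.
    metadata : :class:`GenomeMetadata` covering every genome.
    gene_sets : optional explicit families; derived from the gene-tree
        leaf sets when omitted.
    costs : DTL event costs (duplication 2, transfer 3, loss 1 by default).
    """

    def __init__(self, species_tree: dendropy.Tree,
                 gene_trees: Mapping[str, dendropy.Tree],
                 metadata: GenomeMetadata,
                 gene_sets: Optional[Sequence[GeneSet]] = None,
                 costs: DTLCosts = DTLCosts(),
                 min_taxa: int = 4,
                 require_multi_species: bool = True,
                 keep_large: bool = True,
                 zero_distance_eps: float = 1e-6):
        self.species_tree = binarize(species_tree)
        self.gene_trees = dict(gene_trees)
        self.metadata = metadata
        self.costs = costs
        self.min_taxa = min_taxa
        self.require_multi_species = require_multi_species
        self.keep_large = keep_large
        self.zero_distance_eps = zero_distance_eps
        if gene_sets is None:
            gene_sets = [
                GeneSet(set_id=fam, members=[
                    GeneSetMember(genome_id=g, protein_id=f"{fam}|{g}", length=0)
                    for g in sorted(leaf_labels(t))
                ])
                for fam, t in sorted(self.gene_trees.items())
            ]
        self.gene_sets = list(gene_sets)
        known = set(leaf_labels(self.species_tree))
        for fam, t in self.gene_trees.items():
            stray = set(leaf_labels(t)) - known
            if stray:
                raise ValueError(
                    f"gene tree {fam}: leaves not in species tree: {sorted(stray)}")

    @classmethod
    def from_dataset(cls, ds, **kwargs) -> "HGTAnalysis":
        """Build from a simulated :class:`hgtrecon.simulate.Dataset`."""
        trees = {f: t for f, t in ds.gene_trees.items() if t is not None}
        return cls(ds.species_tree, trees, ds.metadata,
                   gene_sets=ds.gene_sets, **kwargs)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "HGTAnalysis":
        """Build from an on-disk dataset (species.nwk, genes/*.nwk,
        metadata.tsv, genesets.tsv)."""
        from .simulate import load_dataset

        species, meta, gene_trees, gene_sets = load_dataset(path)
        return cls(species, gene_trees, meta,
                   gene_sets=gene_sets or None, **kwargs)

    def fit(self, seed: int = 0) -> "HGTResults":
        """Run filtering, reconciliation and classification."""
        sets_by_id = {gs.set_id: gs for gs in self.gene_sets}
        missing_tree = [sid for sid in sets_by_id if sid not in self.gene_trees]
        if missing_tree:
            raise ValueError(f"gene set(s) without a gene tree: {missing_tree[:5]}")
        kept, removed = filter_gene_sets(
            self.gene_sets, self.metadata, min_taxa=self.min_taxa,
            require_multi_species=self.require_multi_species,
            keep_large=self.keep_large)
        survivors = []
        for gs in kept:
            if gs.has_alignment and zero_distance_filter(gs, self.zero_distance_eps):
                removed.append((gs.set_id, "zero_distance"))
            else:
                survivors.append(gs)
        kept = survivors

        events: list[HGTEvent] = []
        recs: dict[str, Reconciliation] = {}
        set_sites: dict[str, frozenset] = {}
        scopes: dict[str, str] = {}
        for i, gs in enumerate(sorted(kept, key=lambda g: g.set_id)):
            gt = self.gene_trees[gs.set_id]
            st = prune_to_taxa(self.species_tree, set(gs.genomes))
            sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                           % (2**31 - 1))
            rec = reconcile_unrooted(binarize(gt), st, self.costs, seed=sub_seed)
            recs[gs.set_id] = rec
            scope, sites = geneset_scope(gs, self.metadata)
            scopes[gs.set_id] = scope
            set_sites[gs.set_id] = sites
            for t in rec.transfers:
                events.append(annotate_transfer(t, gs.set_id, scope, self.metadata))
        return HGTResults(self, kept, removed, recs, events, set_sites, scopes, seed)


class HGTResults:
    """Fitted results: events, profiles, tallies, selections, summary."""

    def __init__(self, model: HGTAnalysis, kept: list, removed: list,
                 reconciliations: dict, events: list, set_sites: dict,
                 scopes: dict, seed: int):
        self.model = model
        self.kept_sets = kept
        self.removed = removed
        self.reconciliations = reconciliations
        self.events = events
        self.set_sites = set_sites
        self.scopes = scopes
        self.seed = seed
        self.events_frame = events_to_frame(events)
        self.gene_profiles = build_gene_profiles(events, kept, model.metadata)
        self.genome_profiles = build_genome_profiles(events, model.metadata)

    # -- tables -----------------------------------------------------------
    def site_tally(self) -> pd.DataFrame:
        return tally_by_site(self.events, self.model.metadata.sites)

    def pair_tally(self) -> pd.DataFrame:
        return two_site_tally(self.events, self.set_sites)

    def strata_summary(self) -> pd.DataFrame:
        return strata_ratio_summary(self.events, self.gene_profiles)

    # -- gene selections --------------------------------------------------
    def ftg(self) -> list[str]:
        return select_ftg(self.gene_profiles)

    def rtg(self) -> pd.DataFrame:
        return select_rtg(self.gene_profiles)

    def widespread(self, sites) -> list[str]:
        return widespread_genes(self.kept_sets, self.model.metadata, sites)

    def core(self) -> list[str]:
        return core_genes(self.kept_sets, self.model.metadata)

    def markers(self) -> list[str]:
        return marker_candidates(self.gene_profiles, self.kept_sets,
                                 self.model.metadata)

    # -- summary ----------------------------------------------------------
    def composition(self) -> dict:
        """Dataset-composition and headline ratios (full precision)."""
        meta = self.model.metadata
        n_events = len(self.events)
        hgt_sets = sorted(self.events_frame["gene_set_id"].unique()) if n_events else []
        n_hgt = len(hgt_sets)
        n_intra = sum(1 for e in self.events if e.niche == "intra")
        return {
            "n_genomes": len(meta),
            "n_phyla": meta.df["phylum"].nunique(),
            "n_genera": meta.df["genus"].nunique(),
            "n_species": meta.df["species"].nunique(),
            "n_gene_sets": len(self.model.gene_sets),
            "n_analyzed_sets": len(self.kept_sets),
            "n_hgt_genes": n_hgt,
            "n_events": n_events,
            "hgt_genes_per_genome": n_hgt / len(meta) if len(meta) else 0.0,
            "events_per_hgt_gene": n_events / n_hgt if n_hgt else 0.0,
            "n_intra": n_intra,
            "n_inter": n_events - n_intra,
            "intra_pct": 100.0 * n_intra / n_events if n_events else 0.0,
            "median_genome_hgt_index": float(self.genome_profiles["hgt_index"].median()),
        }

    def summary(self) -> str:
        c = self.composition()
        lines = [
            "HGT detection summary",
            "=" * 54,
            f"genomes                {c['n_genomes']:>10d}",
            f"phyla / genera / species  {c['n_phyla']:>4d} / {c['n_genera']} / {c['n_species']}",
            f"gene sets (input/analyzed) {c['n_gene_sets']:>5d} / {c['n_analyzed_sets']}",
            f"HGT-genes              {c['n_hgt_genes']:>10d}",
            f"HGT events             {c['n_events']:>10d}",
            f"HGT-genes per genome   {c['hgt_genes_per_genome']:>13.2f}",
            f"events per HGT-gene    {c['events_per_hgt_gene']:>13.2f}",
            f"intra-niche events     {c['n_intra']:>10d} ({c['intra_pct']:.0f}%)",
            f"inter-niche events     {c['n_inter']:>10d}",
            f"median genome HGT-index {c['median_genome_hgt_index']:>11.2f}",
            "",
            "Per-site tally (a: intra/unique, b: intra/mixed, c=a+b,",
            "                d: inter involving site, e=d/c):",
            self.site_tally().to_string(),
        ]
        return "\n".join(lines)

    def manifest(self) -> dict:
        return {
            "tool": "hgtrecon",
            "version": __version__,
            "seed": self.seed,
            "costs": asdict(self.model.costs),
            "min_taxa": self.model.min_taxa,
            "keep_large": self.model.keep_large,
            "counts": {
                "input_sets": len(self.model.gene_sets),
                "kept_sets": len(self.kept_sets),
                "removed_sets": len(self.removed),
                "reconciliations": len(self.reconciliations),
                "events": len(self.events),
            },
        }

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events_frame.to_csv(out / "events.tsv", sep="\t", index=False)
        self.gene_profiles.to_csv(out / "gene_profiles.tsv", sep="\t", index=False)
        self.genome_profiles.to_csv(out / "genome_profiles.tsv", sep="\t", index=False)
        self.site_tally().to_csv(out / "tally_site.tsv", sep="\t")
        self.pair_tally().to_csv(out / "tally_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(self.removed, columns=["set_id", "reason"]).to_csv(
            out / "removed_sets.tsv", sep="\t", index=False)
        comp = pd.DataFrame([self.composition()])
        comp.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "summary.txt").write_text(self.summary() + "\n")
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2) + "\n")
        return out


def summarize(events, profiles: pd.DataFrame, meta: GenomeMetadata) -> dict:
    """Stand-alone composition summary from an event list, gene profiles
    and metadata (same numbers as :meth:`HGTResults.composition`)."""
    events = list(events)
    n_events = len(events)
    hgt_sets = {e.gene_set_id for e in events}
    n_intra = sum(1 for e in events if e.niche == "intra")
    n_hgt = len(hgt_sets)
    return {
        "n_genomes": len(meta),
        "n_gene_sets": len(profiles),
        "n_hgt_genes": n_hgt,
        "n_events": n_events,
        "hgt_genes_per_genome": n_hgt / len(meta) if len(meta) else 0.0,
        "events_per_hgt_gene": n_events / n_hgt if n_hgt else 0.0,
        "intra_pct": 100.0 * n_intra / n_events if n_events else 0.0,
    }
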