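"""Gene-set data model, metadata, and pre-reconciliation filters.

A *gene set* is a putative orthologous family: one protein per member
genome, optionally with an aligned sequence and a protein-family (Pfam)
assignment.  Before reconciliation, families are filtered the way the
detection pipeline requires: a four-genome minimum (a tree needs four
taxa), removal of single-species families (no species-tree resolution),
optional removal of very large families, and removal of families whose
alignment carries essentially no divergence signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .trees import p_distance

METADATA_COLUMNS = ["genome_id", "species", "genus", "phylum", "body_site", "n_genes"]


class GenomeMetadata:
    """Per-genome metadata table: taxonomy, body site, total gene count.

    Each genome is assigned exactly one body site (strain-level
    mono-residence is assumed; multi-residence is screened separately from
    ANI data, see :mod:`hgtrecon.residence`).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing column(s): {', '.join(missing)}")
        if df["genome_id"].duplicated().any():
            dup = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
            raise ValueError(f"duplicate genome id(s): {dup}")
        if (df["n_genes"] <= 0).any():
            raise ValueError("n_genes must be positive")
        self.df = df.reset_index(drop=True)
        self._site = dict(zip(df["genome_id"], df["body_site"]))
        self._genus = dict(zip(df["genome_id"], df["genus"]))
        self._species = dict(zip(df["genome_id"], df["species"]))
        self._n_genes = dict(zip(df["genome_id"], df["n_genes"]))

    @classmethod
    def from_tsv(cls, path) -> "GenomeMetadata":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df["genome_id"])

    @property
    def sites(self) -> list[str]:
        return sorted(self.df["body_site"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._site

    def site_of(self, genome_id: str) -> str:
        return self._site[genome_id]

    def genus_of(self, genome_id: str) -> str:
        return self._genus[genome_id]

    def species_of(self, genome_id: str) -> str:
        return self._species[genome_id]

    def n_genes_of(self, genome_id: str) -> int:
        try:
            return int(self._n_genes[genome_id])
        except KeyError:
            raise KeyError(f"no gene count recorded for genome {genome_id!r}")


@dataclass(frozen=True)
class GeneSetMember:
    genome_id: str
    protein_id: str
    length: int
    sequence: Optional[str] = None


@dataclass
class GeneSet:
    """A single-copy putative ortholog family."""

    set_id: str
    members: list[GeneSetMember] = field(default_factory=list)
    pfam: Optional[str] = None

    def __post_init__(self):
        genomes = [m.genome_id for m in self.members]
        if len(genomes) != len(set(genomes)):
            raise ValueError(f"gene set {self.set_id}: a genome appears more than once")
        if not self.members:
            raise ValueError(f"gene set {self.set_id}: no members")

    @property
    def genomes(self) -> list[str]:
        return [m.genome_id for m in self.members]

    @property
    def n_taxa(self) -> int:
        return len(self.members)

    @property
    def has_alignment(self) -> bool:
        return all(m.sequence is not None for m in self.members)

    def alignment(self) -> dict[str, str]:
        if not self.has_alignment:
            raise ValueError(f"gene set {self.set_id} has no alignment")
        return {m.genome_id: m.sequence for m in self.members}


def read_gene_sets(members_tsv, fasta_dir=None) -> list[GeneSet]:
    """Load gene sets from a membership TSV (set_id, genome_id, protein_id,
    length) plus optional per-set aligned FASTA files named <set_id>.fasta
    (records keyed by protein id or genome id)."""
    df = pd.read_csv(members_tsv, sep="\t")
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        seqs = {}
        if fasta_dir is not None:
            path = Path(fasta_dir) / f"{set_id}.fasta"
            if path.exists():
                from Bio import SeqIO

                seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        members = [
            GeneSetMember(
                genome_id=str(r.genome_id),
                protein_id=str(r.protein_id),
                length=int(r.length),
                sequence=seqs.get(str(r.protein_id), seqs.get(str(r.genome_id))),
            )
            for r in grp.itertuples()
        ]
        sets.append(GeneSet(set_id=str(set_id), members=members))
    return sets


def filter_gene_sets(
    sets: Sequence[GeneSet],
    meta: GenomeMetadata,
    min_taxa: int = 4,
    require_multi_species: bool = True,
    keep_large: bool = True,
) -> tuple[list[GeneSet], list[tuple[str, str]]]:
    """Apply the pre-reconciliation family filters.

    Families with fewer than *min_taxa* genomes are removed (reason
    ``min_taxa``), as are families whose genomes all belong to one species
    (``single_species``).  With ``keep_large=False`` families spanning more
    than half of all genomes are removed too (``large_set``).  Returns
    (kept, removed) where removed pairs each dropped set id with its
    reason; |kept| + |removed| = |input|.
    """
    n_genomes = len(meta)
    kept: list[GeneSet] = []
    removed: list[tuple[str, str]] = []
    for gs in sets:
        for g in gs.genomes:
            if g not in meta:
                raise KeyError(f"gene set {gs.set_id}: genome {g!r} missing from metadata")
        if gs.n_taxa < min_taxa:
            removed.append((gs.set_id, "min_taxa"))
            continue
        if require_multi_species and len({meta.species_of(g) for g in gs.genomes}) == 1:
            removed.append((gs.set_id, "single_species"))
            continue
        if not keep_large and gs.n_taxa > 0.5 * n_genomes:
            removed.append((gs.set_id, "large_set"))
            continue
        kept.append(gs)
    return kept, removed


def zero_distance_filter(gs: GeneSet, eps: float = 1e-6) -> bool:
    """True if the family should be discarded because every pairwise
    p-distance is below *eps* (no divergence signal to resolve a tree)."""
    dm = p_distance(gs.alignment())
    n = dm.shape[0]
    vals = dm.to_numpy()
    return bool(all(vals[i, j] < eps for i in range(n) for j in range(i + 1, n)))


def select_representative(gs: GeneSet) -> str:
    """Protein id of the member with the lower-median length.

    Length ties are broken by lexicographic protein id, so the choice does
    not depend on member ordering.
    """
    ranked = sorted(gs.members, key=lambda m: (m.length, m.protein_id))
    return ranked[(len(ranked) - 1) // 2].protein_id


def majority_pf(gs: GeneSet, hits: Mapping[str, str]) -> Optional[str]:
    """Family id shared by strictly more than half of the members, else None.

    *hits* maps protein id -> family id and may be partial (proteins with
    no hit count against every family).
    """
    counts: dict[str, int] = {}
    for m in gs.members:
        fam = hits.get(m.protein_id)
        if fam is not None:
            counts[fam] = counts.get(fam, 0) + 1
    if not counts:
        return None
    fam, k = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return fam if k * 2 > gs.n_taxa else None


def geneset_scope(gs: GeneSet, meta: GenomeMetadata) -> tuple[str, frozenset]:
    """('unique'|'mixed', body-site set) of the member genomes.

    A family is *unique* when all members reside in one body site; events
    from unique families are necessarily intra-niche.
    """
    sites = frozenset(meta.site_of(g) for g in gs.genomes)
    return ("unique" if len(sites) == 1 else "mixed"), sites


def read_pfam_hits(path) -> dict[str, str]:
    """Best hit per protein from a TSV (protein_id, family_id, e-value):
    lowest e-value wins, ties by family id."""
    df = pd.read_csv(path, sep="\t")
    best: dict[str, tuple[float, str]] = {}
    for r in df.itertuples():
        key = str(r.protein_id)
        cand = (float(getattr(r, "e_value", 0.0)), str(r.family_id))
        if key not in best or cand < best[key]:
            best[key] = cand
    return {k: v[1] for k, v in best.items()}
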