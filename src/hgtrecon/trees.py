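"""Tree data model and basic phylogenetic operations.

Trees are :class:`dendropy.Tree` objects throughout the package: rooted
reference (species) trees and unrooted gene trees alike.  This module adds
the operations the HGT pipeline needs around them: validated Newick I/O,
deterministic resolution of polytomies, p-distances from protein
alignments, neighbor-joining, and outgroup rooting with outgroup removal.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

GAP_CHARS = frozenset("-.")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or fails validation."""


def parse_newick(text: str, require_unique_labels: bool = True) -> dendropy.Tree:
    """Parse a single semicolon-terminated Newick description.

    Leaf labels become taxon labels; internal node labels are kept as plain
    node annotations (``node.label``).  Duplicate leaf labels are rejected
    unless ``require_unique_labels`` is False (multi-copy gene trees map
    several leaves to the same genome).
    """
    if not text or not text.strip() or text.strip() == ";":
        raise NewickParseError("empty tree description")
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=True)
    if not require_unique_labels:
        # dendropy refuses duplicate taxa; read labels plainly and attach
        # one taxon object per leaf afterwards
        kwargs["suppress_leaf_node_taxa"] = True
    try:
        tree = dendropy.Tree.get(data=text, **kwargs)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if not require_unique_labels:
        for lf in tree.leaf_node_iter():
            if lf.label is None:
                raise NewickParseError("unlabeled leaf in tree")
            lf.taxon = tree.taxon_namespace.new_taxon(label=lf.label)
            lf.label = None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if not labels:
        raise NewickParseError("tree has no labeled leaves")
    if require_unique_labels and len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf label(s): {', '.join(dupes)}")
    for lf in tree.leaf_node_iter():
        if lf.taxon is None:
            raise NewickParseError("unlabeled leaf in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a one-line Newick string (no rooting token)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _leafset_key(node: dendropy.Node) -> tuple[str, ...]:
    return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))


def binarize(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve every polytomy into a caterpillar of zero-length branches.

    Children of a polytomy are ordered by the lexicographic rank of their
    sorted leaf-label sets and folded left-to-right, so the resolution is
    deterministic.  For trees flagged unrooted the basal trifurcation is
    kept (the standard unrooted representation); every other node becomes
    strictly binary.  Already-binary trees come back topologically
    unchanged.
    """
    out = tree.clone(depth=1)
    allow_basal_trifurcation = not out.is_rooted
    for node in out.postorder_node_iter():
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        limit = 3 if (allow_basal_trifurcation and node is out.seed_node) else 2
        if len(kids) <= limit:
            continue
        kids = sorted(kids, key=_leafset_key)
        for k in kids:
            node.remove_child(k)
        while len(kids) > limit:
            joined = dendropy.Node()
            joined.edge.length = 0.0
            joined.add_child(kids[0])
            joined.add_child(kids[1])
            kids = [joined] + kids[2:]
        for k in kids:
            node.add_child(k)
    return out


def _as_sequence_mapping(alignment) -> dict[str, str]:
    if isinstance(alignment, Mapping):
        return {str(k): str(v) for k, v in alignment.items()}
    out: dict[str, str] = {}
    for rec in alignment:  # Bio.SeqRecord iterable or (name, seq) pairs
        if isinstance(rec, (tuple, list)) and len(rec) == 2:
            out[str(rec[0])] = str(rec[1])
        else:
            out[rec.id] = str(rec.seq)
    return out


def p_distance(alignment) -> pd.DataFrame:
    """Pairwise p-distances from a gapped alignment.

    distance = mismatches / columns where both sequences are non-gap.  A
    pair with no comparable column gets distance 1.0 and is recorded in
    ``result.attrs['undefined_pairs']``.  Accepts a mapping name->sequence,
    (name, seq) pairs, or Bio.SeqRecord iterables.
    """
    seqs = _as_sequence_mapping(alignment)
    if len(seqs) < 2:
        raise ValueError("p_distance needs at least 2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must have equal length, got {sorted(lengths)}")
    names = sorted(seqs)
    arr = np.array([list(seqs[n].upper()) for n in names])
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(names)
    d = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gap[i] | gap[j])
            ncomp = int(comparable.sum())
            if ncomp == 0:
                dij = 1.0
                undefined.append((names[i], names[j]))
            else:
                dij = float((arr[i][comparable] != arr[j][comparable]).sum()) / ncomp
            d[i, j] = d[j, i] = dij
    out = pd.DataFrame(d, index=names, columns=names)
    out.attrs["undefined_pairs"] = undefined
    return out


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Classic neighbor-joining on a symmetric distance matrix.

    Taxa are processed in lexicographic order and ties in the Q-matrix are
    broken at the lowest (row, column) index pair, so the output is
    reproducible.  Negative branch-length estimates are clamped to zero
    with a warning.  Returns an unrooted tree (trifurcating seed node).
    """
    taxa = sorted(str(t) for t in dist.index)
    if len(taxa) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    D = dist.loc[taxa, taxa].to_numpy(dtype=float).copy()

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for t in taxa:
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=t)
        nodes.append(nd)

    def _clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(n)] = np.inf  # keep i<j, row-major argmin = lowest (i,j)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    seed = dendropy.Node()
    for k, lk in enumerate(
        (0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02), 0.5 * (d02 + d12 - d01))
    ):
        nodes[k].edge.length = _clamp(lk)
        seed.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def _isolated_copy(tree: dendropy.Tree) -> dendropy.Tree:
    # clone into a private taxon namespace: mutating/purging the copy must
    # never disturb the namespace shared with the source tree
    out = tree.clone(depth=1)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace(),
                                unify_taxa_by_label=False)
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the edge subtending *outgroup*, then remove the outgroup.

    The returned tree is rooted at the attachment point of the outgroup
    (its degree-2 node is suppressed), over the remaining leaves.
    """
    out = _isolated_copy(tree)
    target = None
    for lf in out.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup:
            target = lf
            break
    if target is None:
        avail = ", ".join(sorted(leaf_labels(out)))
        raise ValueError(f"outgroup {outgroup!r} not found; leaves are: {avail}")
    el = target.edge.length
    half = None if el is None else el / 2.0
    out.reroot_at_edge(target.edge, length1=half, length2=half, update_bipartitions=False)
    out.prune_taxa([target.taxon], suppress_unifurcations=True)
    out.purge_taxon_namespace()
    out.is_rooted = True
    return out


def prune_to_taxa(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Restriction of the tree to the given leaves (unary nodes suppressed)."""
    wanted = set(labels)
    have = set(leaf_labels(tree))
    missing = wanted - have
    if missing:
        raise ValueError(f"taxa not in tree: {', '.join(sorted(missing))}")
    out = _isolated_copy(tree)
    out.retain_taxa_with_labels(sorted(wanted))
    out.purge_taxon_namespace()
    out.is_rooted = tree.is_rooted
    return out


def unrooted_rf(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Robinson-Foulds (symmetric difference) between unrooted topologies."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=write_newick(a), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=write_newick(b), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    ta.is_rooted = False
    tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    from dendropy.calculate import treecompare

    return int(treecompare.symmetric_difference(ta, tb))


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length distances (used as additive test matrices)."""
    pdm = tree.phylogenetic_distance_matrix()
    names = sorted(leaf_labels(tree))
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tax[names[i]], tax[names[j]])
    return pd.DataFrame(d, index=names, columns=names)
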