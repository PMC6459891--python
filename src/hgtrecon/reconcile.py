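"""Undated duplication-transfer-loss (DTL) parsimony reconciliation.

Given a rooted binary species tree and a (possibly unrooted) binary gene
tree whose leaves name species-tree leaves, find a minimum-cost embedding
of the gene tree into the species tree under the undated DTL model: each
internal gene node is a speciation (cost 0), a duplication, or a transfer
whose recipient may be any species node incomparable to the donor; genes
skipping species edges pay a loss per edge.  The dynamic program runs over
(gene node, species node) pairs in gene-tree postorder with three
auxiliary quantities per gene node g:

  C(g,s)   cost of embedding the subtree of g with g mapped exactly to s
  IN(g,s)  min over s' at-or-below s of C(g,s') plus a loss per skipped edge
  OUT(g,s) min over s' incomparable to s of C(g,s')

  C(g,s) = min( speciation: IN(a,s_l)+IN(b,s_r) or swapped  [s internal]
              , duplication: D + IN(a,s) + IN(b,s)
              , transfer:    T + min(IN(a,s)+OUT(b,s), IN(b,s)+OUT(a,s)) )

Unrooted gene trees are reconciled by evaluating every rooting (one per
edge) and drawing uniformly, under a caller-supplied seed, among rootings
of globally minimal cost.  Among co-optimal event labelings of a fixed
rooting the backtrack deterministically prefers speciation over
duplication over transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

_TOL = 1e-9
_INF = np.inf


@dataclass(frozen=True)
class DTLCosts:
    """Event costs; speciation is free.  Defaults are the common
    parsimony setting (duplication 2, transfer 3, loss 1)."""

    duplication: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.duplication, self.transfer, self.loss) < 0:
            raise ValueError("DTL costs must be non-negative")


@dataclass(frozen=True)
class TransferRecord:
    """One transfer: the gene node it labels plus the donor and recipient
    species nodes, each represented by its descendant leaf-label set.
    Donor and recipient are always incomparable in the species tree."""

    gene_node: str
    donor: frozenset
    recipient: frozenset


@dataclass
class Reconciliation:
    """A minimum-cost embedding of one gene tree into the species tree."""

    gene_tree: dendropy.Tree
    total_cost: float
    n_speciation: int
    n_duplication: int
    n_transfer: int
    n_loss: int
    mapping: dict = field(default_factory=dict)   # gene node id -> species leafset
    events: dict = field(default_factory=dict)    # internal gene node id -> event
    gene_leafsets: dict = field(default_factory=dict)  # gene node id -> own leafset
    transfers: list = field(default_factory=list)
    n_rootings: int = 1
    optimal_rootings: int = 1


class _SpeciesIndex:
    """Array-indexed view of a rooted binary species tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        self.children = []
        self.leaf_index: dict[str, int] = {}
        self.leafsets: list[frozenset] = []
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            if not kids:
                self.children.append(None)
                self.leaf_index[nd.taxon.label] = i
                self.leafsets.append(frozenset([nd.taxon.label]))
            elif len(kids) == 2:
                ki, kj = idx[id(kids[0])], idx[id(kids[1])]
                self.children.append((ki, kj))
                self.leafsets.append(self.leafsets[ki] | self.leafsets[kj])
            else:
                raise ValueError("species tree must be binary (binarize first)")
        anc = np.zeros((self.n, self.n), dtype=bool)
        for i in range(self.n):  # postorder: children before parents
            anc[i, i] = True
            if self.children[i] is not None:
                for c in self.children[i]:
                    anc[i] |= anc[c]
        self.anc = anc
        self.incomparable = ~(anc | anc.T)
        self.internal = np.array([c is not None for c in self.children])
        ints = np.nonzero(self.internal)[0]
        self.int_idx = ints
        self.int_left = np.array([self.children[i][0] for i in ints], dtype=int)
        self.int_right = np.array([self.children[i][1] for i in ints], dtype=int)


class _GeneTree:
    """Rooted binary gene tree as postorder arrays (leaves carry labels)."""

    def __init__(self, children: dict, labels: dict, root):
        # keys are opaque hashable node ids
        self.post: list = []
        self.children = children
        self.labels = labels
        self.root = root
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self.post.append(node)
                continue
            stack.append((node, True))
            for c in children.get(node, ()):
                stack.append((c, False))
        self.index = {nd: i for i, nd in enumerate(self.post)}
        self.leafsets = {}
        for nd in self.post:
            kids = children.get(nd, ())
            if not kids:
                self.leafsets[nd] = frozenset([labels[nd]])
            else:
                if len(kids) != 2:
                    raise ValueError("gene tree must be binary (binarize first)")
                self.leafsets[nd] = self.leafsets[kids[0]] | self.leafsets[kids[1]]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "_GeneTree":
        children: dict = {}
        labels: dict = {}
        for nd in tree.postorder_node_iter():
            kids = nd.child_nodes()
            if kids:
                children[id(nd)] = [id(k) for k in kids]
            else:
                labels[id(nd)] = nd.taxon.label
        return cls(children, labels, id(tree.seed_node))


def _dp_tables(gt: _GeneTree, S: _SpeciesIndex, costs: DTLCosts):
    """Fill C/IN/OUT for every gene node; returns (C, IN, OUT) dicts of
    arrays indexed by species node."""
    C: dict = {}
    IN: dict = {}
    OUT: dict = {}
    loss = costs.loss
    for nd in gt.post:
        kids = gt.children.get(nd, ())
        if not kids:
            label = gt.labels[nd]
            if label not in S.leaf_index:
                raise KeyError(f"gene leaf {label!r} has no species-tree leaf")
            row = np.full(S.n, _INF)
            row[S.leaf_index[label]] = 0.0
        else:
            a, b = kids
            ina, inb = IN[a], IN[b]
            outa, outb = OUT[a], OUT[b]
            row = np.full(S.n, _INF)
            # speciation at internal species nodes
            sl, sr = S.int_left, S.int_right
            spec = np.minimum(ina[sl] + inb[sr], ina[sr] + inb[sl])
            row[S.int_idx] = spec
            # duplication anywhere
            row = np.minimum(row, costs.duplication + ina + inb)
            # transfer: one child stays at/below s, the other lands incomparable
            row = np.minimum(row, costs.transfer + np.minimum(ina + outb, inb + outa))
        C[nd] = row
        inn = row.copy()
        for s in range(S.n):  # species postorder: children first
            if S.children[s] is not None:
                ci, cj = S.children[s]
                inn[s] = min(inn[s], loss + inn[ci], loss + inn[cj])
        IN[nd] = inn
        masked = np.where(S.incomparable, row[None, :], _INF)
        OUT[nd] = masked.min(axis=1)
    return C, IN, OUT


class _Backtracker:
    def __init__(self, gt: _GeneTree, S: _SpeciesIndex, costs: DTLCosts, C, IN, OUT):
        self.gt, self.S, self.costs = gt, S, costs
        self.C, self.IN, self.OUT = C, IN, OUT
        self.events: dict = {}
        self.mapping: dict = {}
        self.transfers: list[TransferRecord] = []
        self.n_loss = 0

    def _resolve_in(self, nd, s) -> int:
        """Follow the IN chain from s down to the node where nd maps;
        returns that node, counting losses along the way."""
        loss = self.costs.loss
        while True:
            if abs(self.IN[nd][s] - self.C[nd][s]) <= _TOL:
                return s
            ci, cj = self.S.children[s]
            if abs(self.IN[nd][s] - (loss + self.IN[nd][ci])) <= _TOL:
                nxt = ci
            else:
                nxt = cj
            self.n_loss += 1
            s = nxt

    def assign(self, nd, s):
        gt, S, costs = self.gt, self.S, self.costs
        gid = f"g{gt.index[nd]}"
        self.mapping[gid] = S.leafsets[s]
        kids = gt.children.get(nd, ())
        if not kids:
            return
        a, b = kids
        c_here = self.C[nd][s]
        ina, inb = self.IN[a], self.IN[b]
        # preference order at equal cost: speciation > duplication > transfer
        if S.children[s] is not None:
            sl, sr = S.children[s]
            if abs(ina[sl] + inb[sr] - c_here) <= _TOL:
                self.events[gid] = "speciation"
                self._descend(a, self._resolve_in(a, sl))
                self._descend(b, self._resolve_in(b, sr))
                return
            if abs(ina[sr] + inb[sl] - c_here) <= _TOL:
                self.events[gid] = "speciation"
                self._descend(a, self._resolve_in(a, sr))
                self._descend(b, self._resolve_in(b, sl))
                return
        if abs(costs.duplication + ina[s] + inb[s] - c_here) <= _TOL:
            self.events[gid] = "duplication"
            self._descend(a, self._resolve_in(a, s))
            self._descend(b, self._resolve_in(b, s))
            return
        # transfer: decide which child stays
        if abs(costs.transfer + ina[s] + self.OUT[b][s] - c_here) <= _TOL:
            stay, moved = a, b
        else:
            stay, moved = b, a
        self.events[gid] = "transfer"
        cand = np.where(S.incomparable[s], self.C[moved], _INF)
        recip = int(np.argmin(cand))  # lowest index among exact-min ties
        self.transfers.append(
            TransferRecord(gene_node=gid, donor=S.leafsets[s], recipient=S.leafsets[recip])
        )
        self._descend(stay, self._resolve_in(stay, s))
        self._descend(moved, recip)

    def _descend(self, nd, s):
        self.assign(nd, s)


def _reconcile_gt(gt: _GeneTree, S: _SpeciesIndex, costs: DTLCosts,
                  gene_tree: dendropy.Tree) -> Reconciliation:
    C, IN, OUT = _dp_tables(gt, S, costs)
    root_row = C[gt.root]
    best = float(root_row.min())
    s0 = int(np.argmin(root_row))
    bt = _Backtracker(gt, S, costs, C, IN, OUT)
    bt.assign(gt.root, s0)
    ev = list(bt.events.values())
    rec = Reconciliation(
        gene_tree=gene_tree,
        total_cost=best,
        n_speciation=ev.count("speciation"),
        n_duplication=ev.count("duplication"),
        n_transfer=ev.count("transfer"),
        n_loss=bt.n_loss,
        mapping=bt.mapping,
        events=bt.events,
        gene_leafsets={f"g{gt.index[nd]}": gt.leafsets[nd] for nd in gt.post},
        transfers=bt.transfers,
    )
    expected = (costs.duplication * rec.n_duplication
                + costs.transfer * rec.n_transfer
                + costs.loss * rec.n_loss)
    assert abs(expected - best) <= 1e-6, "backtrack inconsistent with DP cost"
    return rec


def reconcile_rooted(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                     costs: DTLCosts = DTLCosts()) -> Reconciliation:
    """Minimum-cost DTL reconciliation of a rooted binary gene tree against
    a rooted binary species tree.  Gene leaves are matched to species
    leaves by label; several gene leaves may share one label (paralogs)."""
    S = _SpeciesIndex(species_tree)
    gt = _GeneTree.from_dendropy(gene_tree)
    return _reconcile_gt(gt, S, costs, gene_tree)


def _unrooted_adjacency(tree: dendropy.Tree):
    """Adjacency view of a gene tree treated as unrooted; a bifurcating
    seed node is suppressed so its edge counts once."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(id(nd), [])
        if nd.is_leaf():
            labels[id(nd)] = nd.taxon.label
        for k in nd.child_nodes():
            adj[id(nd)].append(id(k))
            adj.setdefault(id(k), []).append(id(nd))
    seed = id(tree.seed_node)
    if len(tree.seed_node.child_nodes()) == 2 and seed in adj and len(adj[seed]) == 2:
        u, v = adj.pop(seed)
        adj[u] = [x for x in adj[u] if x != seed] + [v]
        adj[v] = [x for x in adj[v] if x != seed] + [u]
    return adj, labels


def _root_on_edge(adj, labels, u, v) -> _GeneTree:
    children: dict = {}
    order: dict[int, str] = {}

    def build(node, parent):
        kids = [x for x in adj[node] if x != parent]
        if kids:
            children[node] = kids
        return node

    def dfs(node, parent):
        for k in [x for x in adj[node] if x != parent]:
            dfs(k, node)
        build(node, parent)

    dfs(u, v)
    dfs(v, u)
    root = ("root", u, v)
    children[root] = [u, v]
    return _GeneTree(children, labels, root)


def _rooted_dendropy_from(gt: _GeneTree, source: dendropy.Tree) -> dendropy.Tree:
    """Materialize the chosen rooting as a dendropy tree (labels only)."""
    tns = dendropy.TaxonNamespace()

    def build(node):
        nd = dendropy.Node()
        kids = gt.children.get(node, ())
        if not kids:
            nd.taxon = tns.require_taxon(label=gt.labels[node])
        for k in kids:
            nd.add_child(build(k))
        return nd

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=build(gt.root))
    tree.is_rooted = True
    return tree


def reconcile_unrooted(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                       costs: DTLCosts = DTLCosts(), seed: int = 0) -> Reconciliation:
    """Reconcile an unrooted gene tree by trying a rooting on every edge
    and picking uniformly (under *seed*) among minimum-cost rootings."""
    S = _SpeciesIndex(species_tree)
    adj, labels = _unrooted_adjacency(gene_tree)
    if len(labels) < 2:
        raise ValueError("gene tree needs at least 2 leaves")
    edges = []
    seen = set()
    for u in adj:
        for v in adj[u]:
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                edges.append((u, v))
    # deterministic edge order: by the sorted leaf labels reachable from u side
    def edge_key(e):
        u, v = e
        side = _side_leaves(adj, labels, u, v)
        return (tuple(sorted(side)), tuple(sorted(set(labels.values()) - side)))

    edges.sort(key=edge_key)
    rootings = [_root_on_edge(adj, labels, u, v) for u, v in edges]
    costs_per_rooting = []
    tables = []
    for gt in rootings:
        C, IN, OUT = _dp_tables(gt, S, costs)
        costs_per_rooting.append(float(C[gt.root].min()))
        tables.append((C, IN, OUT))
    best = min(costs_per_rooting)
    ties = [i for i, c in enumerate(costs_per_rooting) if abs(c - best) <= _TOL]
    rng = np.random.default_rng(seed)
    choice = int(ties[rng.integers(len(ties))])
    gt = rootings[choice]
    rec = _reconcile_gt(gt, S, costs, _rooted_dendropy_from(gt, gene_tree))
    rec.n_rootings = len(rootings)
    rec.optimal_rootings = len(ties)
    return rec


def _side_leaves(adj, labels, u, v) -> frozenset:
    out = set()
    stack = [(u, v)]
    while stack:
        node, parent = stack.pop()
        if node in labels:
            out.add(labels[node])
        for k in adj[node]:
            if k != parent:
                stack.append((k, node))
    return frozenset(out)


def extract_transfers(rec: Reconciliation) -> list[TransferRecord]:
    """Transfer records of a reconciliation (donor/recipient incomparable
    species nodes, one record per transfer-labeled gene node)."""
    return list(rec.transfers)
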