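"""Independent brute-force oracle for undated DTL parsimony.

Trees are nested tuples of leaf labels, e.g. ``(("A", "B"), ("C", "D"))``.
The minimum reconciliation cost is found by exhaustively enumerating every
assignment of internal gene-tree nodes to species-tree nodes and scoring
each node's cheapest admissible event (speciation / duplication /
transfer) with explicit per-edge loss counting.  No dynamic programming,
no subtree minima: pure enumeration, usable up to ~6-leaf gene trees.
"""

import itertools


class SpeciesOracle:
    def __init__(self, nested):
        self.leaves = []        # leafset per node (postorder)
        self.depth = {}
        self._build(nested, 0)
        self.n = len(self.leaves)

    def _build(self, nested, depth) -> int:
        if isinstance(nested, str):
            self.leaves.append(frozenset([nested]))
        else:
            kids = [self._build(k, depth + 1) for k in nested]
            assert len(kids) == 2, "species oracle trees must be binary"
            self.leaves.append(self.leaves[kids[0]] | self.leaves[kids[1]])
        i = len(self.leaves) - 1
        self.depth[i] = depth
        return i

    def is_anc(self, i, j) -> bool:     # i ancestor-or-equal of j
        return self.leaves[j] <= self.leaves[i]

    def incomparable(self, i, j) -> bool:
        return not self.is_anc(i, j) and not self.is_anc(j, i)

    def dist_down(self, i, j) -> int:
        assert self.is_anc(i, j)
        return self.depth[j] - self.depth[i]

    def in_different_child_subtrees(self, s, s1, s2) -> bool:
        # s1 and s2 strictly below s, separated at s's two child subtrees
        if s1 == s or s2 == s or not (self.is_anc(s, s1) and self.is_anc(s, s2)):
            return False
        lca_leaves = self.leaves[s1] | self.leaves[s2]
        # s is the lca iff no strictly lower node contains both
        for k in range(self.n):
            if self.leaves[k] >= lca_leaves and self.depth[k] > self.depth[s]:
                return False
        return True

    def leaf_index(self, label):
        for i, ls in enumerate(self.leaves):
            if ls == frozenset([label]):
                return i
        raise KeyError(label)


def _gene_postorder(nested):
    """(children list per internal node, labels per leaf, postorder ids)."""
    children = {}
    labels = {}
    counter = itertools.count()

    def build(node):
        i = None
        if isinstance(node, str):
            i = next(counter)
            labels[i] = node
        else:
            kids = [build(k) for k in node]
            assert len(kids) == 2
            i = next(counter)
            children[i] = kids
        return i

    root = build(nested)
    return children, labels, root


def min_cost_rooted(gene_nested, species_nested, dup=2.0, tr=3.0, loss=1.0):
    """Exhaustive minimum DTL cost of a rooted gene tree."""
    S = SpeciesOracle(species_nested)
    children, labels, root = _gene_postorder(gene_nested)
    internal = sorted(children)
    fixed = {i: S.leaf_index(lab) for i, lab in labels.items()}
    best = float("inf")
    for assignment in itertools.product(range(S.n), repeat=len(internal)):
        mapping = dict(fixed)
        mapping.update(zip(internal, assignment))
        total = 0.0
        ok = True
        for g in internal:
            a, b = children[g]
            s, s1, s2 = mapping[g], mapping[a], mapping[b]
            options = []
            if S.is_anc(s, s1) and S.is_anc(s, s2):
                if S.in_different_child_subtrees(s, s1, s2):
                    options.append(loss * (S.dist_down(s, s1) - 1
                                           + S.dist_down(s, s2) - 1))
                options.append(dup + loss * (S.dist_down(s, s1)
                                             + S.dist_down(s, s2)))
            if S.is_anc(s, s1) and S.incomparable(s, s2):
                options.append(tr + loss * S.dist_down(s, s1))
            if S.is_anc(s, s2) and S.incomparable(s, s1):
                options.append(tr + loss * S.dist_down(s, s2))
            if not options:
                ok = False
                break
            total += min(options)
            if total >= best:
                ok = False
                break
        if ok:
            best = min(best, total)
    return best


def _adjacency(nested):
    counter = itertools.count()
    adj = {}
    labels = {}

    def build(node):
        i = next(counter)
        adj[i] = []
        if isinstance(node, str):
            labels[i] = node
        else:
            for k in node:
                j = build(k)
                adj[i].append(j)
                adj[j].append(i)
        return i

    root = build(nested)
    if len(adj[root]) == 2:  # suppress bifurcating root: its edge counts once
        u, v = adj.pop(root)
        adj[u] = [x for x in adj[u] if x != root] + [v]
        adj[v] = [x for x in adj[v] if x != root] + [u]
    return adj, labels


def all_rootings(nested):
    """Every rooted version (as nested tuples) of a tree read as unrooted."""
    adj, labels = _adjacency(nested)

    def subtree(node, parent):
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return labels[node]
        return tuple(subtree(k, node) for k in kids)

    seen = set()
    out = []
    for u in adj:
        for v in adj[u]:
            if (min(u, v), max(u, v)) in seen:
                continue
            seen.add((min(u, v), max(u, v)))
            out.append((subtree(u, v), subtree(v, u)))
    return out


def min_cost_unrooted(gene_nested, species_nested, dup=2.0, tr=3.0, loss=1.0):
    return min(min_cost_rooted(r, species_nested, dup, tr, loss)
               for r in all_rootings(gene_nested))
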