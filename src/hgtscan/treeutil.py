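"""Unrooted trees with branch lengths, plus rooting and bipartitions.

The maximum-likelihood machinery works on a deliberately small unrooted
tree structure (integer nodes, adjacency dict).  Conversion to and from
Newick goes through DendroPy so that all dialect quirks are handled by
an established parser.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np


class UnrootedTree:
    """Unrooted tree: integer nodes, adjacency map node -> {neighbour: length}."""

    def __init__(self) -> None:
        self.nbrs: dict[int, dict[int, float]] = {}
        self.leaf_name: dict[int, str] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------
    def new_node(self, name: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nbrs[nid] = {}
        if name is not None:
            self.leaf_name[nid] = name
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.nbrs[u][v] = length
        self.nbrs[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.nbrs[u][v]
        del self.nbrs[v][u]

    def set_length(self, u: int, v: int, length: float) -> None:
        self.nbrs[u][v] = length
        self.nbrs[v][u] = length

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.nbrs = {u: dict(d) for u, d in self.nbrs.items()}
        t.leaf_name = dict(self.leaf_name)
        t._next_id = self._next_id
        return t

    # -- queries ------------------------------------------------------
    @property
    def node_by_name(self) -> dict[str, int]:
        return {name: nid for nid, name in self.leaf_name.items()}

    def is_leaf(self, u: int) -> bool:
        return u in self.leaf_name

    @property
    def taxa(self) -> set[str]:
        return set(self.leaf_name.values())

    def edges(self):
        for u, d in self.nbrs.items():
            for v in d:
                if u < v:
                    yield u, v

    def internal_edges(self):
        for u, v in self.edges():
            if not self.is_leaf(u) and not self.is_leaf(v):
                yield u, v

    def side_leaves(self, u: int, v: int) -> set[str]:
        """Taxon names on u's side of the edge (u, v)."""
        seen = {v}
        stack = [u]
        out: set[str] = set()
        while stack:
            w = stack.pop()
            if w in seen:
                continue
            seen.add(w)
            if self.is_leaf(w):
                out.add(self.leaf_name[w])
            stack.extend(x for x in self.nbrs[w] if x not in seen)
        return out

    def bipartition_key(self, u: int, v: int, ref: str | None = None) -> frozenset:
        """Canonical key of the split induced by edge (u, v).

        The key is the side NOT containing the reference taxon (by
        default the lexicographically smallest), so both orientations
        map to the same key.
        """
        ref = ref or min(self.taxa)
        side = self.side_leaves(u, v)
        return frozenset(side if ref not in side else self.taxa - side)

    def bipartitions(self, internal_only: bool = True) -> dict[frozenset, tuple[int, int]]:
        ref = min(self.taxa)
        out = {}
        edges = self.internal_edges() if internal_only else self.edges()
        for u, v in edges:
            out[self.bipartition_key(u, v, ref)] = (u, v)
        return out

    def has_clade(self, taxa: set[str]) -> bool:
        """Is there an edge separating exactly ``taxa`` from the rest?"""
        taxa = set(taxa)
        if taxa == self.taxa:
            return True
        if len(taxa) <= 1:
            return True
        for u, v in self.edges():
            side = self.side_leaves(u, v)
            if side == taxa or self.taxa - side == taxa:
                return True
        return False

    def total_length(self) -> float:
        return sum(l for _, d in self.nbrs.items() for l in d.values()) / 2.0

    # -- serialisation ------------------------------------------------
    def newick(self, supports: dict[frozenset, int] | None = None,
               lengths: bool = True) -> str:
        """Newick string; internal-node labels carry bipartition supports."""
        # root the traversal at an internal node (or the only node)
        root = next((u for u in self.nbrs if not self.is_leaf(u)), None)
        if root is None:
            root = next(iter(self.nbrs))
        ref = min(self.taxa) if self.taxa else None

        def fmt(u: int, parent: int | None) -> str:
            children = [v for v in self.nbrs[u] if v != parent]
            if not children:
                label = self.leaf_name.get(u, "")
            else:
                inner = ",".join(fmt(v, u) for v in children)
                label = f"({inner})"
                if supports is not None and parent is not None and not self.is_leaf(u):
                    key = self.bipartition_key(u, parent, ref)
                    if key in supports:
                        label += str(supports[key])
            if parent is not None and lengths:
                label += f":{self.nbrs[u][parent]:.6f}"
            return label

        return fmt(root, None) + ";"

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "UnrootedTree":
        t = cls()
        node_map: dict = {}
        for node in dtree.preorder_node_iter():
            name = node.taxon.label if node.taxon else None
            node_map[node] = t.new_node(name)
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else 0.0
                t.add_edge(node_map[node.parent_node], node_map[node], float(length))
        # suppress a degree-2 root left over from a rooted Newick
        root = node_map[dtree.seed_node]
        if len(t.nbrs[root]) == 2 and root not in t.leaf_name:
            (a, la), (b, lb) = t.nbrs[root].items()
            t.remove_edge(root, a)
            t.remove_edge(root, b)
            del t.nbrs[root]
            t.add_edge(a, b, la + lb)
        return t

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
        return cls.from_dendropy(dtree)


# ---------------------------------------------------------------------------
# rooted view used for placement classification


@dataclass
class RootedNode:
    """Node of an outgroup-rooted tree; ``support`` is the bootstrap
    percentage of the edge above this node (None at the root and for
    leaves)."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list = field(default_factory=list)
    parent: "RootedNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> set[str]:
        if self.is_leaf:
            return {self.name}
        out: set[str] = set()
        for child in self.children:
            out |= child.leaves()
        return out

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def find_leaf(self, name: str) -> "RootedNode":
        for node in self.iter_nodes():
            if node.is_leaf and node.name == name:
                return node
        raise KeyError(f"leaf {name!r} not in tree")


def root_on_edge(tree: UnrootedTree, u: int, v: int,
                 supports: dict[frozenset, int] | None = None) -> RootedNode:
    """Root the unrooted tree on edge (u, v), attaching edge supports."""
    ref = min(tree.taxa)
    supports = supports or {}

    def build(node: int, parent: int, length: float) -> RootedNode:
        rn = RootedNode(name=tree.leaf_name.get(node), length=length)
        if not tree.is_leaf(node):
            rn.support = supports.get(tree.bipartition_key(node, parent, ref))
        for child in tree.nbrs[node]:
            if child != parent:
                crn = build(child, node, tree.nbrs[node][child])
                crn.parent = rn
                rn.children.append(crn)
        return rn

    half = tree.nbrs[u][v] / 2.0
    root = RootedNode()
    for side, other in ((u, v), (v, u)):
        crn = build(side, other, half)
        crn.parent = root
        root.children.append(crn)
    return root


def root_on_outgroup(tree: UnrootedTree, outgroup: set[str],
                     supports: dict[frozenset, int] | None = None):
    """Root on the edge separating the outgroup from everything else.

    If the outgroup is not monophyletic in this tree, roots on the edge
    maximising the number of outgroup taxa isolated on one side, and
    reports ``monophyletic=False``.
    """
    outgroup = set(outgroup) & tree.taxa
    if not outgroup:
        raise ValueError("no outgroup taxon present in tree")
    best, best_score = None, -1
    for u, v in tree.edges():
        side = tree.side_leaves(u, v)
        for og_side in (side, tree.taxa - side):
            inside = len(og_side & outgroup)
            # prefer edges whose one side is pure outgroup
            if og_side <= outgroup and inside > best_score:
                best, best_score = (u, v), inside
    monophyletic = best_score == len(outgroup)
    if best is None:
        # fall back: edge above any single outgroup leaf
        leaf = tree.node_by_name[next(iter(outgroup))]
        nbr = next(iter(tree.nbrs[leaf]))
        best = (leaf, nbr)
        monophyletic = False
    rooted = root_on_edge(tree, *best, supports=supports)
    return rooted, monophyletic


# ---------------------------------------------------------------------------
# neighbour joining starting trees


def jc_distance_matrix(patterns: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances from coded site patterns."""
    n = patterns.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (patterns[i] < 4) & (patterns[j] < 4)
            total = weights[ok].sum()
            if total == 0:
                d = 0.75
            else:
                p = weights[ok & (patterns[i] != patterns[j])].sum() / total
                p = min(p, 0.74)
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = max(d, 1e-6)
    return D


def nj_tree(names: list[str], D: np.ndarray) -> UnrootedTree:
    """Neighbour-joining topology via scikit-bio, as an UnrootedTree."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(names) == 2:
        t = UnrootedTree()
        a = t.new_node(names[0])
        b = t.new_node(names[1])
        t.add_edge(a, b, max(D[0, 1], 1e-6))
        return t
    if len(names) == 3:
        t = UnrootedTree()
        hub = t.new_node()
        for i, name in enumerate(names):
            leaf = t.new_node(name)
            d = max((D[i, (i + 1) % 3] + D[i, (i + 2) % 3] - D[(i + 1) % 3, (i + 2) % 3]) / 2, 1e-6)
            t.add_edge(hub, leaf, d)
        return t
    dm = DistanceMatrix(D, names)
    skb = nj(dm)
    newick = skb.write(_io.StringIO(), format="newick").getvalue()
    tree = UnrootedTree.from_newick(newick)
    for u, d in tree.nbrs.items():
        for v in list(d):
            if d[v] < 1e-6:
                tree.set_length(u, v, 1e-6)
    return tree


def enumerate_topologies(names: list[str], branch_length: float = 0.1):
    """All unrooted binary topologies by sequential edge insertion
    (3 taxa: 1; 4: 3; 5: 15; grows as (2n-5)!!)."""
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")

    def grow(tree: UnrootedTree, remaining: list[str]):
        if not remaining:
            yield tree
            return
        name = remaining[0]
        for u, v in list(tree.edges()):
            t = tree.copy()
            length = t.nbrs[u][v]
            t.remove_edge(u, v)
            mid = t.new_node()
            t.add_edge(u, mid, length / 2)
            t.add_edge(mid, v, length / 2)
            t.add_edge(mid, t.new_node(name), branch_length)
            yield from grow(t, remaining[1:])

    base = UnrootedTree()
    hub = base.new_node()
    for name in names[:3]:
        base.add_edge(hub, base.new_node(name), branch_length)
    yield from grow(base, list(names[3:]))


def random_topology(names: list[str], rng: np.random.Generator,
                    branch_length: float = 0.1) -> UnrootedTree:
    """Random unrooted binary topology by sequential edge attachment."""
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    order = list(names)
    rng.shuffle(order)
    t = UnrootedTree()
    hub = t.new_node()
    for name in order[:3]:
        t.add_edge(hub, t.new_node(name), branch_length)
    for name in order[3:]:
        edges = list(t.edges())
        u, v = edges[rng.integers(0, len(edges))]
        length = t.nbrs[u][v]
        t.remove_edge(u, v)
        mid = t.new_node()
        t.add_edge(u, mid, length / 2)
        t.add_edge(mid, v, length / 2)
        t.add_edge(mid, t.new_node(name), branch_length)
    return t
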