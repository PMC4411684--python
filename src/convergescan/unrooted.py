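"""Light-weight unrooted tree structure for reconciliation and origin calling.

Phylogenies move through the package as newick strings or :mod:`dendropy`
trees; this module gives them an adjacency-list form on which bipartition
(split) extraction, restriction to a leaf subset, and subtree-prune-regraft
(SPR) surgery are straightforward and exactly testable.

A split is represented as a ``frozenset`` of leaf labels — the side of the
bipartition not containing the reference leaf (the lexicographically smallest
label of the whole tree), so split sets of two trees on the same leaf set are
directly comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

__all__ = ["UTree", "canonical_split"]


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonicalize a bipartition side relative to the full leaf set."""
    ref = min(all_leaves)
    if ref in side:
        return frozenset(all_leaves - side)
    return frozenset(side)


@dataclass
class _EdgeData:
    length: float = 1.0
    support: float | None = None


class UTree:
    """Unrooted multifurcating tree with labelled leaves.

    Nodes are integers; leaves carry string labels. Edges may carry a length
    and a support value (bootstrap percentage).
    """

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.label: dict[int, str] = {}
        self.edge_data: dict[frozenset, _EdgeData] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = set()
        if label is not None:
            self.label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float = 1.0,
                 support: float | None = None) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.edge_data[frozenset((u, v))] = _EdgeData(length, support)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.edge_data.pop(frozenset((u, v)), None)

    @classmethod
    def from_newick(cls, newick: str) -> "UTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "UTree":
        ut = cls()
        node_map: dict = {}
        for nd in tree.preorder_node_iter():
            lbl = None
            if nd.is_leaf():
                lbl = nd.taxon.label if nd.taxon else nd.label
            node_map[nd] = ut.new_node(lbl)
            if nd.parent_node is not None:
                support = None
                if not nd.is_leaf() and nd.label is not None:
                    try:
                        support = float(nd.label)
                    except ValueError:
                        support = None
                length = nd.edge.length if nd.edge.length is not None else 1.0
                ut.add_edge(node_map[nd.parent_node], node_map[nd],
                            length=length, support=support)
        root = node_map[tree.seed_node]
        ut._suppress_if_degree_two(root)
        return ut

    def copy(self) -> "UTree":
        ut = UTree()
        ut.adj = {u: set(vs) for u, vs in self.adj.items()}
        ut.label = dict(self.label)
        ut.edge_data = {e: _EdgeData(d.length, d.support)
                        for e, d in self.edge_data.items()}
        ut._next_id = self._next_id
        return ut

    # -- basic queries -------------------------------------------------

    @property
    def leaves(self) -> list[int]:
        return [n for n, nb in self.adj.items() if len(nb) <= 1 and n in self.label]

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self.label[n] for n in self.leaves)

    def degree(self, n: int) -> int:
        return len(self.adj[n])

    def edges(self) -> list[frozenset]:
        return sorted(self.edge_data, key=lambda e: tuple(sorted(e)))

    def side_leaves(self, start: int, blocked: int) -> frozenset:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        out = []
        while stack:
            n = stack.pop()
            if n in self.label and len(self.adj[n]) <= 1:
                out.append(self.label[n])
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(out)

    def split_of_edge(self, edge: frozenset) -> frozenset:
        u, v = tuple(edge)
        return canonical_split(self.side_leaves(v, u), self.leaf_labels)

    def nontrivial_splits(self) -> set:
        """All splits with ≥2 leaves on both sides, canonicalized."""
        all_leaves = self.leaf_labels
        out = set()
        for edge in self.edge_data:
            u, v = tuple(edge)
            side = self.side_leaves(v, u)
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(canonical_split(side, all_leaves))
        return out

    # -- surgery -------------------------------------------------------

    def _suppress_if_degree_two(self, n: int) -> None:
        if self.degree(n) == 2 and n not in self.label:
            a, b = tuple(self.adj[n])
            da = self.edge_data[frozenset((n, a))]
            db = self.edge_data[frozenset((n, b))]
            supp = da.support if da.support is not None else db.support
            self.remove_edge(n, a)
            self.remove_edge(n, b)
            del self.adj[n]
            self.add_edge(a, b, length=da.length + db.length, support=supp)

    def restrict(self, keep_labels) -> "UTree":
        """Tree induced by a subset of leaf labels (degree-2 nodes suppressed)."""
        keep = set(keep_labels)
        ut = self.copy()
        # iteratively strip leaves not kept, then suppress
        changed = True
        while changed:
            changed = False
            for n in list(ut.adj):
                if ut.degree(n) <= 1 and ut.label.get(n) not in keep:
                    for m in list(ut.adj[n]):
                        ut.remove_edge(n, m)
                    del ut.adj[n]
                    ut.label.pop(n, None)
                    changed = True
            for n in list(ut.adj):
                if ut.degree(n) == 2 and n not in ut.label:
                    ut._suppress_if_degree_two(n)
                    changed = True
        return ut

    def relabel(self, mapping: dict) -> "UTree":
        """Return a copy with leaf labels passed through ``mapping``."""
        ut = self.copy()
        for n, lbl in list(ut.label.items()):
            ut.label[n] = mapping.get(lbl, lbl)
        return ut

    def _nodes_on_side(self, start: int, blocked: int) -> set:
        """All nodes reachable from ``start`` without crossing ``blocked``."""
        comp = {start}
        stack = [start]
        while stack:
            n = stack.pop()
            for m in self.adj[n]:
                if m != blocked and m not in comp:
                    comp.add(m)
                    stack.append(m)
        return comp

    def spr_candidates(self):
        """Enumerate SPR moves as (prune_node, prune_from, regraft_edge).

        ``(prune_node, prune_from)`` is a directed edge: the subtree hanging
        from ``prune_node`` away from ``prune_from`` is detached and
        re-attached in the middle of ``regraft_edge``. Regraft edges incident
        to the old attachment point are excluded (null moves).
        """
        for edge in self.edges():
            for prune_node, prune_from in itertools.permutations(tuple(edge)):
                retained = self._nodes_on_side(prune_from, prune_node)
                if sum(1 for n in retained
                       if n in self.label and len(self.adj[n]) <= 1) < 2:
                    continue
                for redge in self.edges():
                    u, v = tuple(redge)
                    if u not in retained or v not in retained:
                        continue
                    if prune_from in redge:
                        continue
                    yield prune_node, prune_from, redge

    def apply_spr(self, prune_node: int, prune_from: int,
                  regraft_edge: frozenset) -> "UTree":
        """Return a new tree with the SPR move applied."""
        ut = self.copy()
        ut.remove_edge(prune_node, prune_from)
        ut._suppress_if_degree_two(prune_from)
        x, y = tuple(regraft_edge)
        d = ut.edge_data[frozenset((x, y))]
        ut.remove_edge(x, y)
        mid = ut.new_node()
        half = d.length / 2.0
        ut.add_edge(x, mid, length=half)
        ut.add_edge(mid, y, length=half)
        ut.add_edge(mid, prune_node, length=1.0)
        return ut

    # -- output --------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string rooted arbitrarily at the highest-degree node."""
        if not self.adj:
            return ";"
        root = max(self.adj, key=lambda n: (self.degree(n), -n))

        def rec(n: int, parent: int | None) -> str:
            children = [m for m in sorted(self.adj[n]) if m != parent]
            if not children:
                return self.label.get(n, "")
            parts = []
            for c in children:
                d = self.edge_data[frozenset((n, c))]
                parts.append(f"{rec(c, n)}:{d.length:.12g}")
            name = self.label.get(n, "")
            return "(" + ",".join(parts) + ")" + name

        return rec(root, None) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"UTree({sorted(self.leaf_labels)})"
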