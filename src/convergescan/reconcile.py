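"""Gene-tree / species-tree reconciliation by bipartition dissimilarity.

A horizontal gene transfer moves a gene lineage onto an unrelated branch of
the species phylogeny, so the gene tree disagrees with the species tree by
(at least) one subtree-prune-regraft (SPR) rearrangement. This module scores
the disagreement as the Robinson–Foulds bipartition dissimilarity and
explains it greedily: at each step the SPR move of the species tree that most
reduces the dissimilarity to the gene tree is applied and recorded as a
candidate transfer. Transfer direction is reported as unresolved — with no
outgroup information on gene presence in the family ancestors, donor and
recipient cannot be told apart.

An exhaustive bounded-depth search (:func:`brute_force_transfers`) serves as
an independent optimality check on small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy

from .unrooted import UTree

__all__ = [
    "TransferEvent",
    "ReconciliationResult",
    "as_utree",
    "bipartitions",
    "bipartition_dissimilarity",
    "infer_transfers",
    "brute_force_transfers",
]


def as_utree(tree) -> UTree:
    """Coerce a newick string, dendropy Tree, or UTree to a UTree."""
    if isinstance(tree, UTree):
        return tree
    if isinstance(tree, dendropy.Tree):
        return UTree.from_dendropy(tree)
    if isinstance(tree, str):
        return UTree.from_newick(tree)
    raise TypeError(f"cannot interpret {type(tree)!r} as a tree")


def bipartitions(tree) -> set:
    """Non-trivial bipartitions (splits) of an unrooted tree.

    Each split is the canonical ``frozenset`` side of the bipartition; a
    fully resolved unrooted n-leaf tree yields n−3 of them, a star tree none.
    """
    return as_utree(tree).nontrivial_splits()


@dataclass(frozen=True)
class TransferEvent:
    """One inferred transfer: an SPR move of the species tree.

    ``recipient_split`` is the leaf set of the moved subtree,
    ``donor_split`` the smaller side of the edge it was regrafted onto
    (computed on the pruned tree). Direction is not resolved: the move is
    symmetric evidence of contact between the two branches.
    """

    donor_split: frozenset
    recipient_split: frozenset
    dissimilarity_drop: int
    order_index: int
    direction_resolved: bool = False

    @property
    def pair(self) -> frozenset:
        """Unordered {donor, recipient} pair, for direction-free comparison."""
        return frozenset((self.donor_split, self.recipient_split))


@dataclass
class ReconciliationResult:
    events: list = field(default_factory=list)
    initial_dissimilarity: int = 0
    final_dissimilarity: int = 0
    converged: bool = False

    @property
    def n_events(self) -> int:
        return len(self.events)


def _map_and_restrict(gene, species, leaf_map=None):
    """Map gene leaves onto species labels and restrict both trees.

    Multi-copy species are collapsed to a single leaf when their copies are
    monophyletic in the gene tree; otherwise each copy becomes its own
    species-tree leaf (the species leaf is expanded into a polytomy).
    """
    g = as_utree(gene)
    s = as_utree(species)
    if leaf_map is None:
        leaf_map = {lbl: lbl for lbl in g.leaf_labels}
    missing = g.leaf_labels - set(leaf_map)
    if missing:
        raise ValueError(f"gene leaves not in leaf map: {sorted(missing)}")

    by_species: dict[str, list[str]] = {}
    for gl, sl in leaf_map.items():
        if gl in g.leaf_labels:
            by_species.setdefault(sl, []).append(gl)

    relabel: dict[str, str] = {}
    drop: set[str] = set()
    expand: dict[str, list[str]] = {}
    g_splits_all = None
    for sl, copies in by_species.items():
        if len(copies) == 1:
            relabel[copies[0]] = sl
            continue
        # monophyly test: does some edge separate exactly these copies?
        if g_splits_all is None:
            g_splits_all = set()
            for e in list(g.edge_data):
                u, v = tuple(e)
                g_splits_all.add(frozenset(g.side_leaves(v, u)))
                g_splits_all.add(frozenset(g.side_leaves(u, v)))
        cset = frozenset(copies)
        if cset in g_splits_all or len(g.leaf_labels - cset) <= 1:
            keep = min(copies)
            relabel[keep] = sl
            drop.update(c for c in copies if c != keep)
        else:
            names = [f"{sl}@{i+1}" for i in range(len(copies))]
            for c, nm in zip(sorted(copies), names):
                relabel[c] = nm
            expand[sl] = names

    g = g.restrict(g.leaf_labels - drop).relabel(relabel)
    if expand:
        s = s.copy()
        for sl, names in expand.items():
            node = next(n for n, lbl in s.label.items() if lbl == sl)
            del s.label[node]
            for nm in names:
                leaf = s.new_node(nm)
                s.add_edge(node, leaf, length=0.0)

    shared = g.leaf_labels & s.leaf_labels
    return g.restrict(shared), s.restrict(shared), shared


def bipartition_dissimilarity(gene, species, leaf_map=None) -> int:
    """Robinson–Foulds split dissimilarity between gene and species tree.

    Both trees are restricted to their shared species (after mapping gene
    copies to species); the value is the size of the symmetric difference of
    their non-trivial split sets. Fewer than four shared leaves leave no
    non-trivial splits, giving 0 with a warning.
    """
    g, s, shared = _map_and_restrict(gene, species, leaf_map)
    if len(shared) < 4:
        warnings.warn("fewer than 4 shared leaves: dissimilarity defined as 0")
        return 0
    return len(g.nontrivial_splits() ^ s.nontrivial_splits())


def _rf(splits_a: set, tree_b: UTree) -> int:
    return len(splits_a ^ tree_b.nontrivial_splits())


def infer_transfers(gene, species, leaf_map=None,
                    max_events: int = 8) -> ReconciliationResult:
    """Greedy SPR minimization of the bipartition dissimilarity.

    Repeatedly applies, to the species tree, the SPR rearrangement with the
    largest dissimilarity drop against the gene tree, recording each applied
    move as a :class:`TransferEvent`. Stops at dissimilarity 0, when no move
    improves, or after ``max_events`` moves. Ties are broken deterministically:
    the move relocating the fewest leaves wins (a transfer moves a single
    lineage), then lexicographically on the (recipient, donor) split pair.
    """
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    g, s, shared = _map_and_restrict(gene, species, leaf_map)
    result = ReconciliationResult()
    if len(shared) < 4:
        warnings.warn("fewer than 4 shared leaves: nothing to reconcile")
        result.converged = True
        return result
    gene_splits = g.nontrivial_splits()
    current = s
    dissim = _rf(gene_splits, current)
    result.initial_dissimilarity = dissim

    def sort_key(labels: frozenset):
        return tuple(sorted(labels))

    step = 0
    while dissim > 0 and step < max_events:
        best = None
        for pn, pf, redge in current.spr_candidates():
            moved = current.apply_spr(pn, pf, redge)
            new_d = _rf(gene_splits, moved)
            drop = dissim - new_d
            if drop <= 0:
                continue
            recipient = current.side_leaves(pn, pf)
            pruned = current.copy()
            pruned.remove_edge(pn, pf)
            pruned._suppress_if_degree_two(pf)
            u, v = tuple(redge)
            side1 = pruned.side_leaves(v, u)
            side2 = pruned.side_leaves(u, v)
            donor = min((side1, side2), key=lambda x: (len(x), sort_key(x)))
            key = (-drop, len(recipient), sort_key(recipient), sort_key(donor))
            if best is None or key < best[0]:
                best = (key, moved, new_d, recipient, donor, drop)
        if best is None:
            break
        _, current, dissim, recipient, donor, drop = best
        result.events.append(TransferEvent(
            donor_split=frozenset(donor), recipient_split=frozenset(recipient),
            dissimilarity_drop=drop, order_index=step))
        step += 1

    result.final_dissimilarity = dissim
    result.converged = dissim == 0
    return result


def brute_force_transfers(gene, species, leaf_map=None,
                          k_max: int = 3) -> int | None:
    """Minimal number of SPR moves reconciling species with gene tree.

    Exhaustive breadth-first search over move sequences up to ``k_max``
    (test oracle; guarded to ≤8 leaves and k_max ≤ 3). Returns the minimum
    move count achieving dissimilarity 0, or ``None`` if none within bound.
    """
    if k_max > 3:
        raise ValueError("k_max limited to 3 for exhaustive search")
    g, s, shared = _map_and_restrict(gene, species, leaf_map)
    if len(shared) > 8:
        raise ValueError("brute force limited to 8 shared leaves")
    if len(shared) < 4:
        return 0
    gene_splits = g.nontrivial_splits()

    def key_of(tree: UTree):
        return frozenset(tree.nontrivial_splits())

    frontier = [s]
    seen = {key_of(s)}
    if _rf(gene_splits, s) == 0:
        return 0
    for depth in range(1, k_max + 1):
        nxt = []
        for tree in frontier:
            for pn, pf, redge in tree.spr_candidates():
                moved = tree.apply_spr(pn, pf, redge)
                k = key_of(moved)
                if k in seen:
                    continue
                seen.add(k)
                if len(k ^ gene_splits) == 0:
                    return depth
                nxt.append(moved)
        frontier = nxt
    return None
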