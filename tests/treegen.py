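"""Random-tree helpers for oracle tests: independent of the package's own
tree structures (plain adjacency dicts built by leaf insertion)."""

from __future__ import annotations

import itertools

import numpy as np


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       bl_low: float = 0.1, bl_high: float = 1.0):
    """Random unrooted binary tree by sequential leaf attachment.

    Returns (newick, labels, D) where D[i, j] is the path distance between
    leaves i and j — an additive matrix by construction.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # adjacency with branch lengths
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}, 2: {}, 3: {}}
    nxt = 4
    center = 3
    for i in range(3):
        w = float(rng.uniform(bl_low, bl_high))
        adj[i][center] = w
        adj[center][i] = w
    leaf_ids = {0: labels[0], 1: labels[1], 2: labels[2]}
    for i in range(3, n_leaves):
        # pick a random edge, split it, hang the new leaf
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid, leaf = nxt, nxt + 1
        nxt += 2
        frac = float(rng.uniform(0.2, 0.8))
        del adj[u][v]; del adj[v][u]
        adj[mid] = {}
        adj[leaf] = {}
        adj[u][mid] = adj[mid][u] = w * frac
        adj[v][mid] = adj[mid][v] = w * (1 - frac)
        bl = float(rng.uniform(bl_low, bl_high))
        adj[leaf][mid] = adj[mid][leaf] = bl
        leaf_ids[leaf] = labels[i]

    # distances by BFS from each leaf
    ids = sorted(leaf_ids)
    D = np.zeros((n_leaves, n_leaves))
    for a_idx, a in enumerate(ids):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for b_idx, b in enumerate(ids):
            D[a_idx, b_idx] = dist[b]
    ordered_labels = [leaf_ids[i] for i in ids]

    def newick_of(node, parent):
        kids = [m for m in adj[node] if m != parent]
        if not kids:
            return leaf_ids[node]
        parts = [f"{newick_of(k, node)}:{adj[node][k]:.6f}" for k in kids]
        return "(" + ",".join(parts) + ")"

    return newick_of(center, None) + ";", ordered_labels, D


def random_topology_newick(rng: np.random.Generator, n_leaves: int) -> str:
    nwk, _, _ = random_binary_tree(rng, n_leaves)
    return nwk


def all_splits_bruteforce(newick: str) -> set:
    """Independent split enumeration: test every leaf subset for being one
    side of an edge by checking both sides induce connected subtrees."""
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    # adjacency over dendropy nodes
    nodes = list(t.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    adj = {i: set() for i in range(len(nodes))}
    for n in nodes:
        if n.parent_node is not None:
            a, b = idx[id(n)], idx[id(n.parent_node)]
            adj[a].add(b); adj[b].add(a)
    # suppress a rooted degree-2 seed node
    root = idx[id(t.seed_node)]
    if len(adj[root]) == 2:
        a, b = tuple(adj[root])
        adj[a].discard(root); adj[b].discard(root)
        adj[a].add(b); adj[b].add(a)
        del adj[root]
    leaf_idx = {lf.taxon.label: idx[id(lf)] for lf in t.leaf_node_iter()}

    out = set()
    ref = min(leaves)
    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    for e in edges:
        u, v = tuple(e)
        # leaves on v's side without crossing u
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            for lbl, li in leaf_idx.items():
                if li == x:
                    side.add(lbl)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= len(leaves) - 2:
            if ref in side:
                side = set(leaves) - side
            out.add(frozenset(side))
    return out
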