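"""Maximum-likelihood protein phylogenetics under WAG with gamma rates.

The substitution process is the Whelan–Goldman (WAG) empirical amino-acid
model with discrete-gamma among-site rate variation (WAG+Γ): the
exchangeability matrix S and stationary frequencies π define the rate matrix
Q_ij = S_ij π_j (i≠j), normalized to one expected substitution per unit
branch length, and each site evolves at one of K equiprobable rates given by
the category means of a Gamma(α, α) distribution.

Tree inference follows the classic pipeline: pairwise ML distances →
neighbor-joining starting tree → nearest-neighbor-interchange (NNI)
hill-climbing with per-branch Brent re-optimization. Node supports come from
nonparametric bootstrap of alignment columns (default 100 replicates).
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats
import dendropy

from ._wag import AA_ORDER, WAG_EXCHANGE, WAG_FREQS
from .msa import MSA, GAP_CHARS
from .unrooted import UTree

__all__ = [
    "SubstModel",
    "discrete_gamma_rates",
    "ml_pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "tree_log_likelihood",
    "nni_search",
    "bootstrap_supports",
]

MAX_BRANCH_LENGTH = 10.0
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of K equiprobable categories of Gamma(shape, shape).

    The category mean over (b_k, b_{k+1}) follows from the incomplete-gamma
    identity E[X; X<b] = P(a+1, a·b) for X ~ Gamma(a, a); rates average 1.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    edges = scipy.stats.gamma.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1 / shape)
    upper = scipy.special.gammainc(shape + 1, shape * edges[1:])
    lower = scipy.special.gammainc(shape + 1, shape * edges[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


class SubstModel:
    """WAG+Γ substitution model with spectral transition probabilities."""

    def __init__(self, exchangeabilities=None, frequencies=None,
                 gamma_shape: float = 1.0, n_categories: int = 4):
        S = np.asarray(exchangeabilities if exchangeabilities is not None
                       else WAG_EXCHANGE, dtype=float)
        pi = np.asarray(frequencies if frequencies is not None
                        else WAG_FREQS, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a 20-vector summing to 1")
        self.freqs = pi / pi.sum()
        self.gamma_shape = float(gamma_shape)
        self.n_categories = int(n_categories)
        self.rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        # symmetric form for a stable eigendecomposition
        sq = np.sqrt(self.freqs)
        A = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((A + A.T) / 2.0)
        self._eigval = w
        self._left = U.T * sq[None, :]          # U^T D^{1/2}
        self._right = U / sq[:, None]           # D^{-1/2} U

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), shape (20, 20)."""
        e = np.exp(self._eigval * t)
        return (self._right * e[None, :]) @ self._left

    def transitions_by_category(self, t: float) -> np.ndarray:
        """Stacked P(r_k · t) for each rate category, shape (K, 20, 20)."""
        return np.stack([self.transition(r * t) for r in self.rates])


def _encode(seq: str) -> np.ndarray:
    """Residues to indices; gaps/unknowns to -1 (missing data)."""
    return np.array([_AA_INDEX.get(c.upper(), -1) if c not in GAP_CHARS else -1
                     for c in seq], dtype=int)


# ---------------------------------------------------------------------------
# pairwise distances

def ml_pairwise_distance(a: str, b: str, model: SubstModel | None = None) -> float:
    """ML branch length between two aligned rows under the model.

    Maximizes Σ_sites log( π_i · mean_k P_k(i→j | t) ) by bounded Brent
    search on t ∈ [0, 10] over shared ungapped columns.
    """
    model = model or SubstModel()
    ea, eb = _encode(a), _encode(b)
    if len(ea) != len(eb):
        raise ValueError("rows must be aligned to equal length")
    mask = (ea >= 0) & (eb >= 0)
    if not mask.any():
        raise ValueError("no shared ungapped columns")
    counts = np.zeros((20, 20))
    np.add.at(counts, (ea[mask], eb[mask]), 1.0)
    if np.array_equal(ea[mask], eb[mask]):
        return 0.0
    logpi = np.log(model.freqs)

    def neg_loglik(t: float) -> float:
        P = model.transitions_by_category(t).mean(axis=0)
        with np.errstate(divide="ignore"):
            ll = counts * (logpi[:, None] + np.log(np.maximum(P, 1e-300)))
        return -ll.sum()

    res = scipy.optimize.minimize_scalar(
        neg_loglik, bounds=(1e-8, MAX_BRANCH_LENGTH), method="bounded",
        options={"xatol": 1e-6})
    return float(res.x)


def distance_matrix(msa: MSA, model: SubstModel | None = None):
    """Pairwise ML distance matrix over MSA rows (labels, ndarray)."""
    model = model or SubstModel()
    labels = list(msa.rows)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(
                msa.rows[labels[i]], msa.rows[labels[j]], model)
    return labels, D


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(D, labels=None) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    On an additive matrix this recovers the generating topology with exact
    branch lengths. Negative estimated lengths are clamped to zero.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.isnan(D).any() or (D[~np.eye(n, dtype=bool)] < 0).any():
        raise ValueError("distance matrix entries must be finite and non-negative")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    ut = UTree()
    nodes = {i: ut.new_node(labels[i]) for i in range(n)}
    active = list(range(n))
    nxt = n
    Dm = {(i, j): D[i, j] for i in range(n) for j in range(n) if i <= j}

    def dist(i, j):
        return Dm[(i, j)] if i <= j else Dm[(j, i)]

    def setdist(i, j, v):
        Dm[(min(i, j), max(i, j))] = v

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * dist(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist(i, j) - li
        u = nxt
        nxt += 1
        nodes[u] = ut.new_node()
        ut.add_edge(nodes[u], nodes[i], length=max(li, 0.0))
        ut.add_edge(nodes[u], nodes[j], length=max(lj, 0.0))
        for k in active:
            if k in (i, j):
                continue
            setdist(u, k, 0.5 * (dist(i, k) + dist(j, k) - dist(i, j)))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = (dist(i, j) + dist(i, k) - dist(j, k)) / 2
    lj = (dist(i, j) + dist(j, k) - dist(i, k)) / 2
    lk = (dist(i, k) + dist(j, k) - dist(i, j)) / 2
    c = ut.new_node()
    ut.add_edge(c, nodes[i], length=max(li, 0.0))
    ut.add_edge(c, nodes[j], length=max(lj, 0.0))
    ut.add_edge(c, nodes[k], length=max(lk, 0.0))

    tree = dendropy.Tree.get(data=ut.to_newick(), schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# likelihood

def _compress_patterns(msa: MSA):
    enc = np.stack([_encode(msa.rows[k]) for k in msa.rows])  # (n_rows, L)
    patterns, counts = np.unique(enc, axis=1, return_counts=True)
    return list(msa.rows), patterns, counts.astype(float)


def _likelihood_engine(ut: UTree, order, patterns, counts, model: SubstModel):
    """Felsenstein pruning over an unrooted tree given encoded patterns."""
    leaves_by_label = {ut.label[n]: n for n in ut.leaves}
    missing = set(order) - set(leaves_by_label)
    extra = set(leaves_by_label) - set(order)
    if missing or extra:
        raise ValueError(
            f"leaf/row mismatch: missing from tree {sorted(missing)}, "
            f"absent from alignment {sorted(extra)}")
    root = max(ut.adj, key=lambda n: ut.degree(n))
    K = model.n_categories
    npat = patterns.shape[1]
    row_of = {lbl: i for i, lbl in enumerate(order)}

    def partial(node: int, parent: int | None) -> np.ndarray:
        out = np.ones((K, npat, 20))
        if node in ut.label and ut.label[node] in row_of:
            states = patterns[row_of[ut.label[node]]]
            obs = states >= 0
            out[:, obs, :] = 0.0
            out[:, obs, states[obs]] = 1.0
        for c in sorted(ut.adj[node]):
            if c == parent:
                continue
            t = ut.edge_data[frozenset((node, c))].length
            child = partial(c, node)
            Pk = model.transitions_by_category(max(t, 0.0))
            out *= np.einsum("kij,kpj->kpi", Pk, child)
        return out

    root_partial = partial(root, None)
    site_lik = np.einsum("i,kpi->kp", model.freqs, root_partial).mean(axis=0)
    return float((counts * np.log(np.maximum(site_lik, 1e-300))).sum())


def tree_log_likelihood(tree, msa: MSA, model: SubstModel | None = None) -> float:
    """Log-likelihood of an alignment on a tree under WAG+Γ.

    Gap and unknown characters contribute all-ones partials (missing data);
    the discrete-gamma mixture is averaged per site. Invariant to the
    rooting of the unrooted topology (reversibility).
    """
    from .reconcile import as_utree
    model = model or SubstModel()
    ut = as_utree(tree)
    order, patterns, counts = _compress_patterns(msa)
    return _likelihood_engine(ut, order, patterns, counts, model)


# ---------------------------------------------------------------------------
# topology search

def _optimize_branches(ut: UTree, order, patterns, counts, model,
                       n_passes: int = 2) -> float:
    """Brent-optimize each branch length in place; returns final logL."""
    ll = -np.inf
    for _ in range(n_passes):
        for edge in ut.edges():
            data = ut.edge_data[edge]

            def neg(t):
                data.length = t
                return -_likelihood_engine(ut, order, patterns, counts, model)

            res = scipy.optimize.minimize_scalar(
                neg, bounds=(1e-8, MAX_BRANCH_LENGTH), method="bounded",
                options={"xatol": 1e-4})
            data.length = float(res.x)
            ll = -res.fun
    return ll


def _nni_alternatives(ut: UTree, edge):
    """The two NNI rearrangements across an internal edge."""
    u, v = tuple(edge)
    if ut.degree(u) < 3 or ut.degree(v) < 3:
        return
    a, b = sorted(m for m in ut.adj[u] if m != v)[:2]
    c, d = sorted(m for m in ut.adj[v] if m != u)[:2]
    for x, y in ((b, c), (b, d)):
        alt = ut.copy()
        la = alt.edge_data[frozenset((u, x))].length
        lb = alt.edge_data[frozenset((v, y))].length
        alt.remove_edge(u, x)
        alt.remove_edge(v, y)
        alt.add_edge(u, y, length=lb)
        alt.add_edge(v, x, length=la)
        yield alt


def nni_search(start, msa: MSA, model: SubstModel | None = None,
               tol: float = 1e-6, max_rounds: int = 20):
    """NNI hill-climbing from a starting tree.

    Each round evaluates both NNI alternatives at every internal edge
    (re-optimizing the swapped edge's length), applies the best improving
    move, and re-optimizes all branch lengths; stops when no move improves
    the log-likelihood by more than ``tol``.

    Returns (tree, logL, trace) where trace is the non-decreasing logL path.
    """
    from .reconcile import as_utree
    model = model or SubstModel()
    ut = as_utree(start).copy()
    order, patterns, counts = _compress_patterns(msa)
    ll = _optimize_branches(ut, order, patterns, counts, model)
    trace = [ll]
    for _ in range(max_rounds):
        best = None
        for edge in ut.edges():
            u, v = tuple(edge)
            if ut.degree(u) < 3 or ut.degree(v) < 3:
                continue
            for alt in _nni_alternatives(ut, edge):
                # re-optimize the central edge only for candidate scoring
                data = alt.edge_data[frozenset((u, v))]

                def neg(t, alt=alt, data=data):
                    data.length = t
                    return -_likelihood_engine(alt, order, patterns, counts, model)

                res = scipy.optimize.minimize_scalar(
                    neg, bounds=(1e-8, MAX_BRANCH_LENGTH), method="bounded",
                    options={"xatol": 1e-4})
                data.length = float(res.x)
                cand_ll = -res.fun
                if cand_ll > ll + tol and (best is None or cand_ll > best[0]):
                    best = (cand_ll, alt)
        if best is None:
            break
        ut = best[1]
        ll = _optimize_branches(ut, order, patterns, counts, model)
        trace.append(ll)
    tree = dendropy.Tree.get(data=ut.to_newick(), schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree, ll, trace


def infer_ml_tree(msa: MSA, model: SubstModel | None = None,
                  refine: bool = True):
    """Distance + NJ tree, optionally NNI-refined. Returns a dendropy Tree."""
    model = model or SubstModel()
    labels, D = distance_matrix(msa, model)
    tree = nj_tree(D, labels)
    if refine and len(labels) >= 4:
        tree, _, _ = nni_search(tree, msa, model)
    return tree


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_supports(msa: MSA, model: SubstModel | None = None,
                       n_replicates: int = 100, seed: int = 0,
                       refine: bool = False) -> dendropy.Tree:
    """Nonparametric bootstrap supports on the tree inferred from an MSA.

    Columns are resampled with replacement and a tree re-inferred per
    replicate (ML distances + NJ, with optional NNI refinement); each
    internal edge of the reference tree is labelled with the percentage of
    replicates containing its bipartition. Internal edges of effectively
    zero length (no signal) are collapsed first; a fully unresolved
    alignment therefore yields a support-free star tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if msa.length < 1:
        raise ValueError("alignment has no columns")
    from .reconcile import as_utree
    model = model or SubstModel()
    rng = np.random.default_rng(seed)

    ref_tree = infer_ml_tree(msa, model, refine=refine)
    ref = as_utree(ref_tree)
    # collapse signal-free internal edges
    for edge in ref.edges():
        if edge not in ref.edge_data:
            continue
        u, v = tuple(edge)
        if ref.degree(u) > 1 and ref.degree(v) > 1 \
                and ref.edge_data[edge].length < 1e-7:
            ref.remove_edge(u, v)
            for m in list(ref.adj[v]):
                d = ref.edge_data[frozenset((v, m))]
                ref.remove_edge(v, m)
                ref.add_edge(u, m, length=d.length, support=d.support)
            del ref.adj[v]

    ref_splits = ref.nontrivial_splits()
    if ref_splits:
        tally = {s: 0 for s in ref_splits}
        for _ in range(n_replicates):
            idx = rng.integers(0, msa.length, size=msa.length)
            boot = msa.select_columns(idx)
            rep_tree = infer_ml_tree(boot, model, refine=refine)
            rep_splits = as_utree(rep_tree).nontrivial_splits()
            for s in ref_splits:
                if s in rep_splits:
                    tally[s] += 1
        all_leaves = ref.leaf_labels
        for edge in ref.edges():
            u, v = tuple(edge)
            if ref.degree(u) > 1 and ref.degree(v) > 1:
                s = ref.split_of_edge(edge)
                if 2 <= len(s) <= len(all_leaves) - 2:
                    ref.edge_data[edge].support = 100.0 * tally[s] / n_replicates

    return _utree_to_dendropy_with_supports(ref)


def _utree_to_dendropy_with_supports(ut: UTree) -> dendropy.Tree:
    root = max(ut.adj, key=lambda n: (ut.degree(n), -n))

    def rec(n, parent):
        children = [m for m in sorted(ut.adj[n]) if m != parent]
        if not children:
            return ut.label.get(n, "")
        parts = []
        for c in children:
            d = ut.edge_data[frozenset((n, c))]
            sub = rec(c, n)
            # internal-node label position carries the edge support
            if sub.endswith(")") and d.support is not None:
                sub += f"{d.support:g}"
            parts.append(f"{sub}:{d.length:.12g}")
        return "(" + ",".join(parts) + ")"

    newick = rec(root, None) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree
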