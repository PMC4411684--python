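"""WAG+Gamma model, distances, NJ, likelihood, NNI search, bootstrap."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest

import treegen
from convergescan._wag import AA_ORDER
from convergescan.msa import MSA
from convergescan.phylo import (
    SubstModel,
    bootstrap_supports,
    discrete_gamma_rates,
    distance_matrix,
    infer_ml_tree,
    ml_pairwise_distance,
    nj_tree,
    nni_search,
    tree_log_likelihood,
)
from convergescan.reconcile import bipartitions, as_utree


@pytest.fixture(scope="module")
def model():
    return SubstModel(gamma_shape=1.0, n_categories=4)


class TestModel:
    def test_transition_rows_sum_to_one_and_detailed_balance(self, model):
        P = model.transition(0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        flux = model.freqs[:, None] * P
        assert np.allclose(flux, flux.T)

    def test_mean_rate_is_one_substitution_per_unit(self, model):
        # -sum_i pi_i Q_ii == 1 after normalization
        assert -np.sum(model.freqs * np.diag(model.Q)) == pytest.approx(1.0)

    def test_gamma_category_rates_average_one(self):
        for shape in (0.3, 1.0, 4.0):
            r = discrete_gamma_rates(shape, 4)
            assert r.mean() == pytest.approx(1.0)
            assert np.all(np.diff(r) > 0)

    def test_single_category_collapses_to_homogeneous(self):
        assert discrete_gamma_rates(0.5, 1).tolist() == [1.0]


def _simulate_pair(model, t, length, seed):
    rng = np.random.default_rng(seed)
    a = rng.choice(20, size=length, p=model.freqs)
    P = model.transitions_by_category(t)
    cats = rng.integers(0, model.n_categories, size=length)
    b = np.array([rng.choice(20, p=P[cats[i], a[i]]) for i in range(length)])
    to_str = lambda arr: "".join(AA_ORDER[i] for i in arr)
    return to_str(a), to_str(b)


class TestPairwiseDistance:
    def test_identical_rows_give_zero(self, model):
        assert ml_pairwise_distance("ACDEF", "ACDEF", model) == 0.0

    def test_recovers_simulated_divergence(self, model):
        a, b = _simulate_pair(model, 0.5, 10_000, seed=0)
        est = ml_pairwise_distance(a, b, model)
        assert abs(est - 0.5) < 0.05

    def test_returned_point_is_local_optimum(self, model):
        a, b = _simulate_pair(model, 0.3, 500, seed=1)
        t_hat = ml_pairwise_distance(a, b, model)

        def loglik(t):
            P = model.transitions_by_category(t).mean(axis=0)
            idx = {c: i for i, c in enumerate(AA_ORDER)}
            return sum(math.log(model.freqs[idx[x]] * P[idx[x], idx[y]])
                       for x, y in zip(a, b))

        eps = 1e-3
        assert loglik(t_hat) >= loglik(t_hat + eps) - 1e-9
        assert loglik(t_hat) >= loglik(max(t_hat - eps, 1e-9)) - 1e-9

    def test_gap_only_overlap_rejected(self, model):
        with pytest.raises(ValueError):
            ml_pairwise_distance("A--", "-C-", model)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(D, ["A", "B", "C", "D"])
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        ut = as_utree(tree)
        # pendant branch lengths recovered exactly
        lengths = {ut.label[n]: ut.edge_data[frozenset((n, next(iter(ut.adj[n]))))].length
                   for n in ut.leaves}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        ut = as_utree(nj_tree(D, ["a", "b", "c"]))
        lengths = {ut.label[n]: ut.edge_data[frozenset((n, next(iter(ut.adj[n]))))].length
                   for n in ut.leaves}
        assert lengths == {"a": 0.5, "b": 1.5, "c": 2.5}

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        _, labels, D = treegen.random_binary_tree(rng, 7)
        t1 = nj_tree(D, labels)
        perm = rng.permutation(len(labels))
        t2 = nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert bipartitions(t1) == bipartitions(t2)

    @pytest.mark.parametrize("n_leaves", [4, 6, 9, 12])
    def test_exact_recovery_on_additive_matrices(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            nwk, labels, D = treegen.random_binary_tree(rng, n_leaves)
            tree = nj_tree(D, labels)
            assert bipartitions(tree) == bipartitions(nwk)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        D = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(D, ["a", "b", "c"])


def _enumeration_loglik(newick, msa, model):
    """Independent oracle: sum over all internal-state assignments, with
    transition matrices from scipy's generic matrix exponential."""
    from scipy.linalg import expm
    ut = as_utree(newick)
    idx = {c: i for i, c in enumerate(AA_ORDER)}
    internal = [n for n in ut.adj if n not in ut.label]
    leaves = {n: ut.label[n] for n in ut.leaves}
    Ps = {}
    for k, r in enumerate(model.rates):
        for e, d in ut.edge_data.items():
            Ps[(k, e)] = expm(model.Q * r * d.length)
    total = 0.0
    root = internal[0]
    # orient every edge away from the root
    oriented = []
    stack, seen = [root], {root}
    while stack:
        u = stack.pop()
        for v in ut.adj[u]:
            if v not in seen:
                seen.add(v)
                oriented.append((u, v, frozenset((u, v))))
                stack.append(v)
    for col in range(msa.length):
        site = 0.0
        for k in range(model.n_categories):
            for states in itertools.product(range(20), repeat=len(internal)):
                assign = dict(zip(internal, states))
                for n, lbl in leaves.items():
                    assign[n] = idx[msa.rows[lbl][col]]
                p = model.freqs[assign[root]]
                for u, v, e in oriented:
                    p *= Ps[(k, e)][assign[u], assign[v]]
                site += p / model.n_categories
        total += math.log(site)
    return total


class TestLikelihood:
    def test_zero_branch_two_leaf_limit_is_log_pi(self, model):
        msa = MSA({"x": "W", "y": "W"})
        ll = tree_log_likelihood("(x:1e-9,y:1e-9);", msa, model)
        pi_w = model.freqs[AA_ORDER.index("W")]
        assert ll == pytest.approx(math.log(pi_w), abs=1e-5)

    def test_two_leaf_mixture_matches_matrix_exponential(self, model):
        from scipy.linalg import expm
        msa = MSA({"x": "A", "y": "R"})
        t = 0.37
        ll = tree_log_likelihood(f"(x:{t/2},y:{t/2});", msa, model)
        ia, ir = AA_ORDER.index("A"), AA_ORDER.index("R")
        direct = np.mean([
            model.freqs[ia] * expm(model.Q * r * t)[ia, ir]
            for r in model.rates])
        assert ll == pytest.approx(math.log(direct), abs=1e-9)

    def test_matches_state_enumeration_on_small_trees(self, model):
        msa = MSA({"a": "ARN", "b": "AGN", "c": "SRN", "d": "ARC"})
        nwk = "((a:0.2,b:0.35):0.1,c:0.4,d:0.15);"
        mine = tree_log_likelihood(nwk, msa, model)
        oracle = _enumeration_loglik(nwk, msa, model)
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_invariant_under_rerooting(self, model):
        msa = MSA({"a": "ARND", "b": "AGND", "c": "SRNC", "d": "ARQC"})
        t1 = "((a:0.2,b:0.3):0.1,(c:0.25,d:0.15):0.2);"
        t2 = "((c:0.25,d:0.15):0.3,a:0.2,b:0.3);"  # same unrooted tree
        assert tree_log_likelihood(t1, msa, model) == pytest.approx(
            tree_log_likelihood(t2, msa, model), abs=1e-9)

    def test_one_category_equals_homogeneous_model(self):
        msa = MSA({"a": "ARND", "b": "AGNC", "c": "SRND"})
        nwk = "(a:0.2,b:0.3,c:0.4);"
        m1 = SubstModel(gamma_shape=1.0, n_categories=1)
        m2 = SubstModel(gamma_shape=123.0, n_categories=1)  # shape irrelevant
        assert tree_log_likelihood(nwk, msa, m1) == pytest.approx(
            tree_log_likelihood(nwk, msa, m2))

    def test_label_mismatch_reported(self, model):
        msa = MSA({"a": "A", "b": "R"})
        with pytest.raises(ValueError, match="c"):
            tree_log_likelihood("(a:0.1,c:0.1);", msa, model)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_agrees_with_phangorn(self, model, tmp_path):
        rows = {"t1": "ARNDCQEGHIKL", "t2": "ARNDCEEGHIKV",
                "t3": "ARNECQEGWIKL", "t4": "TRNDCQEGHIKL"}
        (tmp_path / "a.fasta").write_text(
            "".join(f">{k}\n{v}\n" for k, v in rows.items()))
        nwk = "((t1:0.1,t2:0.2):0.05,t3:0.3,t4:0.15);"
        (tmp_path / "t.nwk").write_text(nwk + "\n")
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(phangorn));'
             f'd<-read.phyDat("{tmp_path}/a.fasta",format="fasta",type="AA");'
             f't<-read.tree("{tmp_path}/t.nwk");'
             'cat(pml(t,d,model="WAG",k=4,shape=1.0)$logLik)'],
            capture_output=True, text=True, check=True)
        assert tree_log_likelihood(nwk, MSA(rows), model) == pytest.approx(
            float(r.stdout.strip()), abs=1e-4)


def _simulate_alignment(model, newick, length, seed):
    """Simulate an alignment down a tree (test-local, simple)."""
    rng = np.random.default_rng(seed)
    ut = as_utree(newick)
    root = next(n for n in ut.adj if ut.degree(n) >= 2)
    cats = rng.integers(0, model.n_categories, size=length)
    seqs = {}

    def walk(node, parent, state):
        if parent is not None:
            t = ut.edge_data[frozenset((node, parent))].length
            new = state.copy()
            for k in range(model.n_categories):
                P = model.transition(model.rates[k] * t)
                C = P.cumsum(axis=1)
                sites = np.where(cats == k)[0]
                u = rng.random(sites.size)
                new[sites] = (C[state[sites]] < u[:, None]).sum(axis=1)
            state = new
        if node in ut.label:
            seqs[ut.label[node]] = "".join(AA_ORDER[i] for i in state)
        for m in sorted(ut.adj[node]):
            if m != parent:
                walk(m, node, state)

    walk(root, None, rng.choice(20, size=length, p=model.freqs))
    return MSA(seqs)


class TestSearchAndBootstrap:
    def test_quartet_recovered_from_wrong_start(self, model):
        true = "((a:0.08,b:0.08):0.3,(c:0.08,d:0.08):0.3);"
        msa = _simulate_alignment(model, true, 2000, seed=3)
        wrong = "((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1);"
        tree, ll, trace = nni_search(wrong, msa, model)
        assert bipartitions(tree) == {frozenset({"c", "d"})} or \
            bipartitions(tree) == {frozenset({"a", "b"})}
        # exhaustive check: the recovered topology is the ML quartet
        lls = {}
        for nwk in ("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);",
                    "((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1);",
                    "((a:0.1,d:0.1):0.1,(b:0.1,c:0.1):0.1);"):
            t2, l2, _ = nni_search(nwk, msa, model)
            lls[frozenset(map(tuple, map(sorted, bipartitions(t2))))] = l2
        best_topo = max(lls, key=lls.get)
        assert frozenset(map(tuple, map(sorted, bipartitions(tree)))) == best_topo
        assert ll >= trace[0]

    def test_logl_trace_is_nondecreasing(self, model):
        true = "((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);"
        msa = _simulate_alignment(model, true, 300, seed=4)
        _, _, trace = nni_search("((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1);",
                                 msa, model)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_true_topology_is_stable_under_search(self, model):
        true = "((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3,(e:0.1,f:0.1):0.3);"
        msa = _simulate_alignment(model, true, 1500, seed=5)
        tree, _, _ = nni_search(true, msa, model)
        assert bipartitions(tree) == bipartitions(true)

    def test_identical_sequences_yield_unresolved_star(self, model):
        msa = MSA({k: "ARNDARND" for k in "abcd"})
        tree = bootstrap_supports(msa, model, n_replicates=5, seed=0)
        assert bipartitions(tree) == set()

    def test_deep_split_gets_high_support(self, model):
        true = "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5);"
        msa = _simulate_alignment(model, true, 1000, seed=6)
        tree = bootstrap_supports(msa, model, n_replicates=100, seed=1)
        ut = as_utree(tree)
        supports = [d.support for d in ut.edge_data.values()
                    if d.support is not None]
        assert supports and min(supports) >= 95

    def test_bootstrap_deterministic_given_seed(self, model):
        true = "((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);"
        msa = _simulate_alignment(model, true, 200, seed=7)
        t1 = bootstrap_supports(msa, model, n_replicates=20, seed=9)
        t2 = bootstrap_supports(msa, model, n_replicates=20, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
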