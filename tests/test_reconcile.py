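"""Bipartitions, RF dissimilarity, greedy SPR transfers, brute-force oracle."""

import itertools

import numpy as np
import pytest

import treegen
from convergescan.reconcile import (
    as_utree,
    bipartition_dissimilarity,
    bipartitions,
    brute_force_transfers,
    infer_transfers,
)
from convergescan.worked_examples import (
    XC138_EXPECTED_EVENTS,
    XC138_GENE_NEWICK,
    XC138_SPECIES_NEWICK,
)


class TestBipartitions:
    def test_quartet_has_single_forced_split(self):
        assert bipartitions("((A,B),(C,D));") == {frozenset({"C", "D"})}

    def test_caterpillar_two_nontrivial_splits(self):
        # splits AB|CDE and ABC|DE, canonicalized to the side without A
        got = bipartitions("((((A,B),C),D),E);")
        assert got == {frozenset({"C", "D", "E"}), frozenset({"D", "E"})}

    def test_star_tree_has_none(self):
        assert bipartitions("(A,B,C,D,E);") == set()

    def test_resolved_tree_has_n_minus_3(self):
        rng = np.random.default_rng(0)
        for n in (4, 6, 8, 10):
            nwk = treegen.random_topology_newick(rng, n)
            assert len(bipartitions(nwk)) == n - 3


class TestDissimilarity:
    def test_identical_topologies_zero(self):
        nwk = "((A,B),(C,(D,E)));"
        assert bipartition_dissimilarity(nwk, nwk) == 0

    def test_conflicting_quartets_distance_two(self):
        assert bipartition_dissimilarity("((A,B),(C,D));",
                                         "((A,C),(B,D));") == 2

    def test_matches_independent_split_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            t1 = treegen.random_topology_newick(rng, n)
            t2 = treegen.random_topology_newick(rng, n)
            expected = len(treegen.all_splits_bruteforce(t1)
                           ^ treegen.all_splits_bruteforce(t2))
            assert bipartition_dissimilarity(t1, t2) == expected

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(2)
        trees = [treegen.random_topology_newick(rng, 7) for _ in range(6)]
        for a, b in itertools.combinations(trees, 2):
            assert bipartition_dissimilarity(a, b) == \
                bipartition_dissimilarity(b, a)
        for a in trees:
            assert bipartition_dissimilarity(a, a) == 0
        for a, b, c in itertools.combinations(trees, 3):
            assert bipartition_dissimilarity(a, c) <= \
                bipartition_dissimilarity(a, b) + bipartition_dissimilarity(b, c)

    def test_too_few_shared_leaves_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert bipartition_dissimilarity("((A,B),C);", "((A,C),B);") == 0

    def test_multicopy_monophyletic_copies_collapse(self):
        gene = "(((X1,X2),H),(P,M));"   # two copies in species X, sisters
        species = "(((X,H),P),(M,O));"
        leaf_map = {"X1": "X", "X2": "X", "H": "H", "P": "P", "M": "M"}
        assert bipartition_dissimilarity(gene, species, leaf_map) == 0

    def test_multicopy_nonmonophyletic_expands_species_leaf(self):
        gene = "((X1,H),(X2,(P,M)));"   # copies in X are not sisters
        species = "(((X,H),P),(M,O));"
        leaf_map = {"X1": "X", "X2": "X", "H": "H", "P": "P", "M": "M"}
        d = bipartition_dissimilarity(gene, species, leaf_map)
        assert d > 0  # discordance from the scattered copies


def _apply_known_spr(rng, n):
    """Start tree + tree after one recorded SPR move (ground truth)."""
    start = as_utree(treegen.random_topology_newick(rng, n))
    moves = list(start.spr_candidates())
    pn, pf, redge = moves[rng.integers(len(moves))]
    return start, start.apply_spr(pn, pf, redge)


class TestInferTransfers:
    def test_equal_trees_converge_with_no_events(self):
        nwk = "((A,B),(C,(D,E)));"
        res = infer_transfers(nwk, nwk)
        assert res.n_events == 0 and res.converged

    def test_xc138_two_transfers_between_named_lineages(self):
        res = infer_transfers(XC138_GENE_NEWICK, XC138_SPECIES_NEWICK)
        assert res.n_events == 2 and res.converged
        assert {e.pair for e in res.events} == set(XC138_EXPECTED_EVENTS)
        assert all(not e.direction_resolved for e in res.events)
        assert all(e.dissimilarity_drop > 0 for e in res.events)

    def test_xc138_brute_force_confirms_two_is_minimal(self):
        assert brute_force_transfers(XC138_GENE_NEWICK,
                                     XC138_SPECIES_NEWICK, k_max=2) == 2

    def test_single_spr_perturbations_recovered_in_one_event(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(15):
            n = int(rng.integers(6, 9))
            species, gene = _apply_known_spr(rng, n)
            d = bipartition_dissimilarity(gene, species)
            if d == 0:
                continue  # move was topology-neutral
            res = infer_transfers(gene, species)
            assert res.converged
            assert res.n_events == 1
            assert brute_force_transfers(gene, species, k_max=1) == 1
            checked += 1
        assert checked >= 8

    def test_greedy_count_matches_brute_force_on_two_move_instances(self):
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(12):
            species = as_utree(treegen.random_topology_newick(rng, 8))
            gene = species
            for _ in range(2):
                moves = list(gene.spr_candidates())
                pn, pf, redge = moves[rng.integers(len(moves))]
                gene = gene.apply_spr(pn, pf, redge)
            bf = brute_force_transfers(gene, species, k_max=2)
            if bf is None or bf == 0:
                continue
            res = infer_transfers(gene, species)
            assert res.converged
            assert res.n_events >= bf  # greedy never beats the optimum
            assert res.n_events == bf  # and matches it on small instances
            checked += 1
        assert checked >= 5

    def test_events_strictly_decrease_dissimilarity(self):
        rng = np.random.default_rng(5)
        species = as_utree(treegen.random_topology_newick(rng, 8))
        gene = species
        for _ in range(3):
            moves = list(gene.spr_candidates())
            pn, pf, redge = moves[rng.integers(len(moves))]
            gene = gene.apply_spr(pn, pf, redge)
        res = infer_transfers(gene, species)
        drops = [e.dissimilarity_drop for e in res.events]
        assert all(d > 0 for d in drops)
        assert res.initial_dissimilarity - sum(drops) == \
            res.final_dissimilarity

    def test_deterministic_event_sequence(self):
        r1 = infer_transfers(XC138_GENE_NEWICK, XC138_SPECIES_NEWICK)
        r2 = infer_transfers(XC138_GENE_NEWICK, XC138_SPECIES_NEWICK)
        assert [(e.recipient_split, e.donor_split) for e in r1.events] == \
            [(e.recipient_split, e.donor_split) for e in r2.events]

    def test_brute_force_guards(self):
        rng = np.random.default_rng(6)
        big = treegen.random_topology_newick(rng, 10)
        with pytest.raises(ValueError):
            brute_force_transfers(big, big, k_max=2)
        with pytest.raises(ValueError):
            brute_force_transfers("((A,B),(C,D));", "((A,B),(C,D));", k_max=5)
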