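"""Origin calling, convergence evidence, tallies, and the report table."""

import importlib.resources

import numpy as np
import pytest

from convergescan.classify import (
    ClusterReportRow,
    classify_cluster_origin,
    classify_origin,
    detect_convergence,
    load_reference_table,
    read_cluster_table,
    tally_origins,
    write_cluster_table,
)

LEP_TREE = "(((EPV1,EPV2),Lep1),(Lep2,Bact1));"
LEP_ANN = {"EPV1": "focal_A", "EPV2": "focal_A", "Lep1": "Lepidoptera",
           "Lep2": "Lepidoptera", "Bact1": "Bacteria"}


class TestClassifyOrigin:
    def test_lepidopteran_sister_forces_lepidoptera_label(self):
        call = classify_origin(LEP_TREE, LEP_ANN, "A", support_min=50)
        assert call.origin_label == "Insecta (Lepidoptera)"

    def test_no_cellular_homolog_means_viral_origin(self):
        tree = "((EPV1,EPV2),(BV1,OV1));"
        ann = {"EPV1": "focal_A", "EPV2": "focal_A",
               "BV1": "focal_B", "OV1": "Virus"}
        assert classify_origin(tree, ann, "A").origin_label == "Virus"
        assert classify_cluster_origin(tree, ann).origin_label == "Virus"

    def test_mixed_insect_sisters_generalize_to_insecta(self):
        tree = "((EPV1,EPV2),Lep1,Dip1);"
        ann = {"EPV1": "focal_A", "EPV2": "focal_A", "Lep1": "Lepidoptera",
               "Dip1": "Diptera"}
        assert classify_origin(tree, ann, "A").origin_label == "Insecta"

    def test_low_support_collapses_to_wider_context(self):
        # Lepidoptera sister attached by a weakly supported edge: after
        # collapse the polytomy mixes Lepidoptera and Bacteria
        tree = "(((EPV1,EPV2)100,Lep1)20,Bact1,Vert1);"
        ann = {"EPV1": "focal_A", "EPV2": "focal_A", "Lep1": "Lepidoptera",
               "Bact1": "Bacteria", "Vert1": "Vertebrata"}
        strong = classify_origin(tree, ann, "A", support_min=0)
        weak = classify_origin(tree, ann, "A", support_min=50)
        assert strong.origin_label == "Insecta (Lepidoptera)"
        assert weak.origin_label == "Unknown"

    def test_invariant_to_rerooting_and_leaf_order(self):
        variants = [
            "(((EPV1,EPV2),Lep1),(Lep2,Bact1));",
            "((Lep2,Bact1),(Lep1,(EPV2,EPV1)));",
            "(Lep1,(EPV1,EPV2),(Bact1,Lep2));",
        ]
        labels = {classify_origin(v, LEP_ANN, "A").origin_label
                  for v in variants}
        assert labels == {"Insecta (Lepidoptera)"}

    def test_no_focal_leaves_is_an_error(self):
        with pytest.raises(ValueError):
            classify_origin("((Lep1,Lep2),Bact1);",
                            {"Lep1": "Lepidoptera", "Lep2": "Lepidoptera",
                             "Bact1": "Bacteria"}, "A")

    def test_combined_clade_inside_insects_reads_insect_origin(self):
        # intermixed A/B copies inside the insect clade: the host context,
        # not the other virus family, decides the cluster-level label
        tree = "((H1,(H2,((A1,B1),(A2,B2)))),H3,H4);"
        ann = {"H1": "Lepidoptera", "H2": "Lepidoptera", "H3": "Lepidoptera",
               "H4": "Lepidoptera", "A1": "focal_A", "A2": "focal_A",
               "B1": "focal_B", "B2": "focal_B"}
        assert classify_cluster_origin(tree, ann).origin_label == \
            "Insecta (Lepidoptera)"

    def test_different_entry_contexts_give_compound_label(self):
        tree = "(((EPV1,Lep1),(BV1,Bact1)),Vert1);"
        ann = {"EPV1": "focal_A", "BV1": "focal_B", "Lep1": "Lepidoptera",
               "Bact1": "Bacteria", "Vert1": "Vertebrata"}
        label = classify_cluster_origin(tree, ann).origin_label
        assert set(label.split("/")) == {"Insecta (Lepidoptera)", "Bacteria"}


class TestDetectConvergence:
    def test_disjoint_clades_are_two_acquisitions(self):
        tree = "(((EPV1,EPV2),Lep1),((BV1,BV2),Lep2),Out1);"
        ann = {"EPV1": "focal_A", "EPV2": "focal_A", "BV1": "focal_B",
               "BV2": "focal_B", "Lep1": "Lepidoptera",
               "Lep2": "Lepidoptera", "Out1": "Bacteria"}
        call = detect_convergence(tree, ann)
        assert call.evidence == "separate_clades"
        assert call.independent_acquisitions == 2

    def test_family_nested_in_other_family_is_recent_hgt(self):
        tree = "((MySEV,(XecnGV,HearGV)),((HAEV,PsunGV),CcchNPV));"
        ann = {"MySEV": "focal_A", "HAEV": "focal_A", "XecnGV": "focal_B",
               "HearGV": "focal_B", "PsunGV": "focal_B", "CcchNPV": "focal_B"}
        assert detect_convergence(tree, ann).evidence == \
            "recent_inter_family_HGT"

    def test_reciprocal_monophyly_is_single_entry(self):
        tree = "(((A1,A2),(B1,B2)),Lep1,Bact1);"
        ann = {"A1": "focal_A", "A2": "focal_A", "B1": "focal_B",
               "B2": "focal_B", "Lep1": "Lepidoptera", "Bact1": "Bacteria"}
        call = detect_convergence(tree, ann)
        assert call.evidence == "single_ancient_acquisition"
        assert call.independent_acquisitions == 1

    def test_one_family_absent_is_an_error(self):
        with pytest.raises(ValueError):
            detect_convergence("((A1,A2),Lep1);",
                               {"A1": "focal_A", "A2": "focal_A",
                                "Lep1": "Lepidoptera"})


class TestTableAndTally:
    def test_bundled_table_headline_counts(self):
        t = tally_origins(load_reference_table())
        assert (t.insect, t.eukaryote_non_metazoan, t.bacteria, t.virus,
                t.core) == (15, 3, 7, 7, 1)
        assert t.total_shared == 33
        assert t.total_accessory == 32

    def test_round_trip_is_byte_identical(self):
        raw = (importlib.resources.files("convergescan") / "data"
               / "shared_cluster_table.tsv").read_text()
        assert write_cluster_table(read_cluster_table(raw)) == raw

    def test_removing_a_row_decrements_exactly_one_class(self):
        rows = load_reference_table()
        full = tally_origins(rows)
        for drop in (1, 9, 24, 27):  # one row from each origin class
            t = tally_origins(rows[:drop] + rows[drop + 1:])
            diffs = [full.insect - t.insect,
                     full.eukaryote_non_metazoan - t.eukaryote_non_metazoan,
                     full.bacteria - t.bacteria, full.virus - t.virus,
                     full.core - t.core]
            assert sorted(diffs) == [0, 0, 0, 0, 1]

    def test_empty_input_gives_zero_tally(self):
        t = tally_origins([])
        assert t.total_shared == 0 and t.total_accessory == 0

    def test_unknown_label_raises(self):
        rows = [ClusterReportRow("mystery gene", "1e-10", False,
                                 "Archaea", "-")]
        with pytest.raises(ValueError, match="Archaea"):
            tally_origins(rows)

    def test_x_marks_and_cellular_similarity_counts(self):
        rows = load_reference_table()
        assert sum(r.in_other_large_dsDNA for r in rows) == 21
        viral_only = sum(r.putative_origin == "Virus" for r in rows)
        assert len(rows) - viral_only == 26

    def test_written_order_is_stable_under_shuffle(self):
        rows = load_reference_table()
        rng = np.random.default_rng(0)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        assert write_cluster_table(shuffled) == write_cluster_table(rows)
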