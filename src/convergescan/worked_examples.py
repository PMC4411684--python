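"""Worked phylogenetic instances for the xc138 gene family.

The xc138 family (named after XecnGV orf138) is the flagship case of a
recent gene exchange between the two focal virus families: the gene tree
groups the entomopoxvirus MySEV with the granulovirus pair XecnGV/HearGV,
and the entomopoxvirus HAEV with the granulovirus PsunGV, while the species
phylogeny keeps the two entomopoxviruses together and the granuloviruses
together. Two distant nucleopolyhedrovirus homologs (CcchNPV, OlNPV) anchor
the backbone; without them the two rearrangements collapse into one.

Reconciling these trees requires exactly two transfers: one connecting
MySEV with the XecnGV/HearGV ancestor and one connecting HAEV with PsunGV.
"""

XC138_SPECIES_NEWICK = (
    "((MySEV,HAEV),(((XecnGV,HearGV),PsunGV),(CcchNPV,OlNPV)));"
)

XC138_GENE_NEWICK = (
    "((MySEV,(XecnGV,HearGV)),((HAEV,PsunGV),(CcchNPV,OlNPV)));"
)

# family membership of each taxon: the entomopoxviruses (family A) versus
# the baculoviruses (family B)
XC138_FAMILY = {
    "MySEV": "A",
    "HAEV": "A",
    "XecnGV": "B",
    "HearGV": "B",
    "PsunGV": "B",
    "CcchNPV": "B",
    "OlNPV": "B",
}

# the two transfers, as unordered {moved-lineage, partner-clade} label pairs
XC138_EXPECTED_EVENTS = [
    frozenset((frozenset(("MySEV",)), frozenset(("XecnGV", "HearGV")))),
    frozenset((frozenset(("HAEV",)), frozenset(("PsunGV",)))),
]
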