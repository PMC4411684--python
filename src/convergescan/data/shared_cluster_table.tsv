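cluster_name	best_cross_family_evalue	in_other_large_dsDNA	putative_origin	figure_ref
DNA polymerase	6e-09	X	-	-
bro gene family protein	9e-26	X	Bacteria	S1
helicase 2	1e-67	X	Bacteria	S2
matrixin metalloproteinase	1e-09	X	Bacteria	S3
nla gene he65 (AcMNPV orf105)	8e-97	-	Bacteria	S4
protein tyrosine phosphatase 2 (ptp-2)	2e-33	X	Bacteria	S5
putative phage antirepressor	9e-26	X	Bacteria	S6
unknown LdMNPV orf129	2e-57	-	Bacteria	S7
chitin binding protein (AcMNPV orf145)	1e-17	X	Insecta	S8
Cu/Zn superoxide dismutase	4e-56	X	Insecta	2b/S9
inhibitor of apoptosis	4e-79	X	Insecta	S10
MTG motif gene family protein	7e-10	X	Insecta	S11
ubiquitin	6e-38	X	Insecta	S12
unknown AcMNPV orf7	5e-09	-	Insecta	S13
unknown XecnGV orf106	3e-13	X	Insecta	S14
unknown XecnGV orf22	6e-103	X	Insecta	S15
acetyltransferase	7e-13	-	Insecta (Lepidoptera)	S16
protein phosphatase 1, regulatory subunit 15A	5e-15	X	Insecta (Lepidoptera)	S17
ribonucleotide reductase small subunit homolog	8e-134	X	Insecta (Lepidoptera)	2a/S18
unknown XecnGV orf72	8e-133	-	Insecta (Lepidoptera)	S19
protein tyrosine phosphatase 1 (ptp-1)	4e-41	X	Insecta (Lepidoptera) & Eukaryote	S20
DNA photolyase	3e-140	X	Bilateria/Insecta (Lepidoptera)	S21
dUTPase	1e-43	X	Insecta/Unknown	S22
unknown ClanGV orf085	9e-17	X	Eukaryote	S23
leucine rich gene family protein	4e-27	-	Unicellular eukaryote	S24
fusolin/spindlin/gp37 (AcMNPV orf64)	4e-67	-	Unicellular eukaryote (Amoebozoa)	2c/S25
conotoxin-like protein	3e-20	-	Virus	S26
p35/p49 apoptosis inhibitor	4e-30	-	Virus	S27
unknown AcMNPV orf18	8e-11	-	Virus	S28
unknown AdorNPV orf110	8e-11	X	Virus	S29
unknown AgseGV orf4	7e-103	-	Virus	NA
unknown ChocGV orf11	3e-14	-	Virus	NA
unknown XecnGV orf138	0	X	Virus	1a
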