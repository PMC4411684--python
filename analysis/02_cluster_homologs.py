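#!/usr/bin/env python
"""Cluster the simulated viral proteomes into homologous groups.

All-vs-all Smith-Waterman with Karlin-Altschul e-values (threshold 1e-6),
single-linkage components, and the shared-by-both-families subset. Reads the
output of 01_simulate_dataset.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from Bio import SeqIO

from convergescan import homology

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "simulation"


def main() -> None:
    # header layout is id|family=X|taxon=Y
    prots = []
    for rec in SeqIO.parse(SIM / "viral_proteins.fasta", "fasta"):
        parts = rec.description.split("|")
        fam = next(p.split("=")[1] for p in parts if p.startswith("family="))
        prots.append((parts[0], fam, str(rec.seq)))

    g = homology.build_similarity_graph(prots, threshold=1e-6)
    clusters = homology.cluster_components(g)
    shared = homology.find_shared_clusters(clusters)

    with open(ROOT / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tmember_id\tfamily\n")
        for c in clusters:
            for m in c.member_ids:
                fh.write(f"{c.cluster_id}\t{m}\t{g.nodes[m]['family']}\n")
    with open(ROOT / "clusters_shared.tsv", "w") as fh:
        fh.write("cluster_id\tn_members\tfamilies\n")
        for c in shared:
            fh.write(f"{c.cluster_id}\t{len(c.member_ids)}\t"
                     f"{','.join(sorted(c.families_present))}\n")

    print(f"{len(prots)} proteins -> {len(clusters)} clusters "
          f"({g.number_of_edges()} significant pairs)")
    print(f"{len(shared)} cluster(s) shared by both families: "
          f"{[c.cluster_id for c in shared]}")
    print(f"wrote {ROOT}/clusters.tsv, {ROOT}/clusters_shared.tsv")


if __name__ == "__main__":
    main()
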