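#!/usr/bin/env python
"""Profile-search each shared cluster against the reference database.

Aligns cluster members, builds a PSSM, scores every reference protein
(hosts, bacterial outgroup, unrelated-virus outgroup), and bins significant
hits into the six taxonomic categories with the top-20 cap.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from Bio import SeqIO

from convergescan import profiles
from convergescan.msa import MSA

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "simulation"
EVALUE = 1e-6


def main() -> None:
    seqs = {}
    for rec in SeqIO.parse(SIM / "viral_proteins.fasta", "fasta"):
        seqs[rec.description.split("|")[0]] = str(rec.seq)
    db, taxon_of = {}, {}
    for rec in SeqIO.parse(SIM / "reference_proteins.fasta", "fasta"):
        parts = rec.description.split("|")
        db[parts[0]] = str(rec.seq)
        taxon_of[parts[0]] = parts[1].split("=")[1]

    bin_tag = {"H": "host", "B": "bacteria", "O": "insect_large_dsDNA_virus"}
    shared = [line.split("\t")[0] for line in
              (ROOT / "clusters_shared.tsv").read_text().strip().split("\n")[1:]]
    members_of = {}
    for line in (ROOT / "clusters.tsv").read_text().strip().split("\n")[1:]:
        cid, mid, _fam = line.split("\t")
        members_of.setdefault(cid, []).append(mid)

    report = {}
    for cid in shared:
        member_seqs = {m: seqs[m] for m in members_of[cid]}
        if len({len(s) for s in member_seqs.values()}) == 1:
            msa = MSA(member_seqs)
        else:
            msa = profiles.progressive_align(member_seqs)
        prof = profiles.build_profile(msa)
        hits = [h for h in profiles.profile_search(prof, db)
                if h.e_value <= EVALUE]
        taxmap = {h.hit_id: bin_tag[taxon_of[h.hit_id][0]] for h in hits}
        binned = profiles.bin_by_taxonomy(hits, taxmap)
        report[cid] = {
            cat.value: [[h.hit_id, round(h.score, 2), h.e_value]
                        for h in lst]
            for cat, lst in binned.by_category.items() if lst}
        n_hits = sum(len(v) for v in report[cid].values())
        print(f"{cid}: profile {prof.length} columns, "
              f"{n_hits} significant reference hit(s) in "
              f"{sorted(report[cid])}")

    (ROOT / "profile_hits.json").write_text(json.dumps(report, indent=1))
    print(f"wrote {ROOT}/profile_hits.json")


if __name__ == "__main__":
    main()
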