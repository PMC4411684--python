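# Methods

`convergescan` asks whether two phylogenetically unrelated families of
large dsDNA insect viruses — in the motivating system, entomopoxviruses
(family A) and baculoviruses (family B) — have *independently* acquired
homologous accessory genes, and whether some of those genes have moved
*between* the families by horizontal gene transfer (HGT). Because the
families share no common ancestor, any homologous gene present in both is
informative: it must reflect either convergent acquisition from external
sources or an inter-family exchange. The pipeline identifies the shared
gene clusters, reconstructs each cluster's phylogeny together with its
cellular and viral homologs, and reads acquisition histories off the trees.

## Pipeline

1. **Homolog clustering** (`homology`). Every focal-family protein is
   aligned against every other by Smith–Waterman local alignment (affine
   gaps, BLOSUM62 with X as a score-0 wildcard, gap cost 11 + k via
   Biopython's `PairwiseAligner`). Scores become e-values through the
   Karlin–Altschul formula E = K·m·n·e^(−λS) with the classic
   gapped-BLOSUM62 constants λ = 0.267, K = 0.041 (configurable); m is the
   query length and n the total residue count of the protein set. Pairs
   with E ≤ 10⁻⁶ are edges of an undirected similarity graph (the better of
   the two query directions decides). Homologous groups are the connected
   components — single linkage, chosen to mirror the "any significant hit
   joins the group" behaviour of iterative profile search. Groups
   containing both families are the *shared clusters*.

2. **Profile search** (`profiles`). Each shared cluster is aligned
   (progressive alignment: UPGMA guide tree over pairwise global-alignment
   score deficits, profile–profile Needleman–Wunsch merging with a linear
   column gap cost of −4) and summarized as a position-specific scoring
   matrix: column probabilities (counts + w·background)/(n + w) with
   pseudocount weight w = 1 and a uniform background, log-odds scored. The
   PSSM has no insert/delete states, so database search is the best
   gapless local diagonal run (DP with floor 0); scores are natural
   log-odds, so λ = 1 in the e-value. Nucleotide contigs can be brought
   into the database by six-frame ORF translation (ATG to stop, standard
   code, default minimum 30 aa). Hits are binned into six taxonomic
   categories (insect large dsDNA virus, non-insect large dsDNA virus,
   invertebrate, vertebrate, plant, bacteria), keeping the 20 best per
   category so downstream trees stay small.

3. **Phylogenetics** (`phylo`). Trees are inferred under WAG+Γ: the
   Whelan–Goldman exchangeability matrix S and stationary frequencies π
   define Q_ij = S_ij·π_j, normalized to one expected substitution per
   unit branch length; among-site rate variation uses K = 4 equiprobable
   discrete-gamma categories with category means from the incomplete-gamma
   identity (shape default 1.0). Pairwise distances maximize the two-taxon
   likelihood by bounded Brent search on [0, 10] substitutions/site; the
   topology comes from neighbor joining on those distances and is refined
   by nearest-neighbor-interchange hill climbing (candidate moves scored
   after re-optimizing the swapped edge; the accepted tree gets two full
   Brent passes over all branch lengths; terminate when no move gains more
   than 10⁻⁶ log-likelihood). Site likelihoods use Felsenstein pruning
   with gaps as missing data. Node support is the nonparametric bootstrap
   (resample columns, re-infer, count bipartitions; 100 replicates by
   default); internal branches of effectively zero length are collapsed
   first so an alignment without signal reports no support at all rather
   than spurious 100s.

4. **Reconciliation** (`reconcile`, `unrooted`). HGT detection compares the
   gene tree against the species tree by bipartition dissimilarity — the
   Robinson–Foulds symmetric difference of non-trivial splits after both
   trees are restricted to their shared species. A transfer is modelled as
   one subtree-prune-regraft (SPR) of the species tree; the greedy search
   repeatedly applies the SPR with the largest dissimilarity drop, with
   deterministic tie-breaking (fewest leaves moved first — a transfer moves
   a single lineage — then lexicographic on the induced splits). Multi-copy
   species are collapsed to one leaf when their copies are monophyletic and
   expanded into per-copy species leaves otherwise. Transfer direction is
   reported as unresolved: without knowing gene presence in the family
   ancestors, donor and recipient cannot be distinguished. A bounded
   exhaustive search over SPR sequences (≤ 8 leaves, ≤ 3 moves) provides an
   independent minimality check.

5. **Classification and report** (`classify`). Each gene tree's leaves are
   annotated with taxonomy (hierarchy: Lepidoptera ⊂ Insecta ⊂ Bilateria ⊂
   Metazoa ⊂ Eukaryote, plus Bacteria and Virus). Edges below the support
   threshold (default 50, the lowest support band worth displaying) are
   collapsed into polytomies first. The cluster-level origin walks outward
   from each maximal clade of combined focal-family copies to its nearest
   non-focal sister leaves; the origin is the most specific hierarchy label
   covering the cellular sisters, "Virus" if the tree holds no cellular
   sequence, and a compound "label1/label2" when distinct clades have
   distinct entry contexts. A per-family variant (`classify_origin`) treats
   the other family's copies as viral context, which is the reading used
   for recent-transfer cases. Convergence evidence is one of:
   `separate_clades` (each family's copies form their own clade with their
   own sister context — convergent acquisition, ≥ 2 entry points),
   `recent_inter_family_HGT` (one family nests inside the other's clade),
   or `single_ancient_acquisition` (one combined clade with one entry
   point). Because the families are unrelated, the last pattern still
   implies at least one inter-family exchange after the single acquisition
   — vertical descent cannot carry a gene across families — and the
   pipeline's transfer flag counts it as such.

## Synthetic-data generator

The generator (`simulate`) supplies ground truth for every stage. It is
not a fit to any dataset; its rates are free parameters.

* **Trees.** Three independent birth–death trees (birth 1.0, death 0.2 per
  lineage-time), conditioned on their extant tip counts (default 6 hosts,
  6 + 6 viruses), made properly ultrametric by extending the tips by the
  waiting time to the next event, then scaled to a root-to-tip height of
  0.5 expected substitutions/site — deep enough for real phylogenetic
  structure, shallow enough that homology search is non-trivial but
  reliable. Each viral leaf gets a host range of 1–3 uniformly drawn host
  leaves.
* **Gene families.** A family originates in the host clade, a 3-leaf
  bacterial outgroup, a 3-leaf unrelated-virus outgroup, or natively at one
  family's root (default mix 0.4/0.15/0.15/0.15/0.15). External families
  enter the viral trees through ≥ 1 gain (extra gains Poisson with rate
  `gain_rate` per unit total viral branch length — this is what makes
  convergent double acquisition possible); on viral branches the gene is
  lost at `loss_rate` and transferred at `hgt_rate` per unit branch time,
  only to contemporaneous non-carrying viral branches whose host ranges
  intersect (the mixed-infection contact model). Events are processed on a
  single chronological queue, so "who carries the gene at time t" is always
  consistent.
* **Sequences.** The event history implies a gene genealogy (source-tree
  backbone with viral subtrees hanging at gain points, transfer subtrees at
  transfer points). The root sequence is drawn from WAG stationary
  frequencies, each site gets one fixed gamma category, and substitutions
  follow P(r·t) branch by branch. No insertions or deletions are simulated,
  so each family's copies are aligned by construction and the alignment
  stage can be validated independently. One seed drives named substreams
  (trees / histories / per-family sequences), so a serialized event log
  plus the seed regenerates byte-identical FASTA.

What the generator does **not** emulate: indels and alignment error,
compositional heterogeneity and codon effects, paralogy within a genome
(a branch can carry at most one copy), incomplete taxon sampling biases,
and database noise (contaminated or mislabelled reference sequences).
Passing recovery tests therefore demonstrate the *inferential* machinery —
clustering, tree building, reconciliation, origin walking — under a model
matched to the inference assumptions, not robustness to real-data mess.

## Recovery experiment

`experiments.recovery_experiment` measures ground-truth recovery over 20
independent replicates (6 + 6 + 6 leaves, 6 families, 500-residue
proteins, hgt_rate 2.0 giving a few cross-family transfers per replicate):

* a family counts as a **true transfer case** when it has ≥ 1 cross-family
  transfer whose signal survives to the tips (both families carry it);
  it is **detected** when its cluster is shared and flagged by the
  transfer evidence above;
* a **host-origin family** counts as recovered when its cluster's origin
  label names Insecta;
* the same seeds rerun with hgt_rate = 0 are the false-positive control.

One control ambiguity is intrinsic and worth stating: two successive gains
drawn from the *same* unsampled donor branch produce a gene-tree topology
identical to gain-plus-transfer. No topological method can separate these;
the generator makes such serial gains possible, so occasional control
seeds carry an unavoidable false transfer call.

## Numerical choices and degenerate inputs

* Branch lengths are capped at 10 substitutions/site; Brent tolerance
  1e-6 (pairwise) / 1e-4 (tree branch optimization).
* Likelihoods clamp site probabilities at 1e-300 before the log.
* NJ clamps negative estimated branch lengths to 0 (cannot occur on
  additive input); Q-matrix ties break on the lower taxon index pair.
* Equal-length sequence sets skip the progressive aligner (they are
  aligned by construction in the generator's indel-free model).
* Alignments with < 4 usable taxa get a star tree; identical sequences
  yield a support-free star from the bootstrap.
* Fewer than 4 shared leaves make the bipartition dissimilarity 0 (with a
  warning) — there are no non-trivial splits to compare.
* Greedy reconciliation stops at dissimilarity 0, at `max_events`
  (default 8), or when no move improves; every accepted event strictly
  decreases the dissimilarity, so termination is guaranteed.

## Known limitations

* The greedy SPR search can overcount transfers when moves interact; the
  brute-force check is limited to ≤ 8 leaves and ≤ 3 moves.
* RF dissimilarity treats all splits equally; a refined partial-split
  matching dissimilarity is a noted extension point.
* The NNI + NJ search is adequate for the ≤ 50-taxon trees this analysis
  produces, not a replacement for a full ML search program on large
  alignments; external trees can be supplied as newick wherever a tree is
  consumed.
* Origin calling depends on reference sampling: an origin is only callable
  if homologs of the true source group are present in the database, and
  the nearest-sister rule inherits any taxon-sampling bias.
* The pipeline orchestrator runs on generated datasets (or any
  `SimDataset`-shaped inputs); file-based end-to-end runs are composed
  from the CLI stage commands (`cluster`, `search`, `tree`, `reconcile`),
  which all consume standard formats.
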