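"""All-vs-all protein similarity graph and homologous-group clustering.

Every protein of the two focal virus families is locally aligned against
every other (Smith–Waterman, affine gaps, BLOSUM62), alignment scores are
converted to e-values with the Karlin–Altschul formula E = K·m·n·e^(−λS),
and pairs below the e-value threshold (default 1e-6) become edges of an
undirected similarity graph. Homologous groups are its connected components
(single-linkage: any significant hit joins two groups, mirroring the
behaviour of iterative profile search). Groups containing members of both
families are the shared clusters of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "Cluster",
    "local_align",
    "estimate_evalue",
    "build_similarity_graph",
    "cluster_components",
    "find_shared_clusters",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _blosum62_x0():
    """BLOSUM62 with X scored 0 against everything (wildcard)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m[a, "X"] = 0.0
        m["X", a] = 0.0
    return m


@dataclass
class ScoringScheme:
    """Scores and Karlin–Altschul constants for local alignment.

    Defaults: BLOSUM62 with affine gap cost 11 + k (open 11, extend 1) and
    the classic λ = 0.267, K = 0.041 constants for that scoring.
    """

    substitution_matrix: object = field(default_factory=_blosum62_x0)
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = self.substitution_matrix
        # first gapped residue costs open+extend, later ones extend
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    aligned_span: int
    query_length: int = 0


def _validate_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = sorted(set(seq.upper()) - STANDARD_AA - {"X"})
    if bad:
        raise ValueError(f"{name}: non-standard residues {bad}")


def local_align(a: str, b: str, scheme: ScoringScheme | None = None,
                query_id: str = "query", subject_id: str = "subject") -> AlignmentHit:
    """Best Smith–Waterman local alignment of two proteins.

    The score floor of local alignment is 0 (empty alignment); X is a
    score-0 wildcard. The span is the aligned query length of the best
    alignment.
    """
    scheme = scheme or ScoringScheme()
    _validate_protein(a, "a")
    _validate_protein(b, "b")
    aligner = scheme.aligner()
    a, b = a.upper(), b.upper()
    score = aligner.score(a, b)
    span = 0
    if score > 0:
        aln = next(iter(aligner.align(a, b)))
        qstart, qend = aln.aligned[0][0][0], aln.aligned[0][-1][1]
        span = int(qend - qstart)
    raw = int(round(score))
    bit = (scheme.karlin_lambda * raw - math.log(scheme.karlin_K)) / math.log(2)
    return AlignmentHit(query_id, subject_id, raw, bit, math.inf, span,
                        query_length=len(a))


def estimate_evalue(hit: AlignmentHit | float, db_residues: int,
                    scheme: ScoringScheme | None = None,
                    query_residues: int | None = None) -> float:
    """Karlin–Altschul expected hit count E = K·m·n·exp(−λ·score).

    ``m`` is the query length (taken from the hit unless given), ``n`` the
    total residue count of the database searched.
    """
    scheme = scheme or ScoringScheme()
    if db_residues <= 0:
        raise ValueError("db_residues must be positive")
    if isinstance(hit, AlignmentHit):
        score = hit.raw_score
        m = query_residues if query_residues is not None else hit.query_length
    else:
        score = float(hit)
        m = query_residues
    if not m or m <= 0:
        raise ValueError("query length must be positive")
    return scheme.karlin_K * m * db_residues * math.exp(
        -scheme.karlin_lambda * score)


def build_similarity_graph(proteins, scheme: ScoringScheme | None = None,
                           threshold: float = 1e-6) -> nx.Graph:
    """All-vs-all similarity graph over tagged proteins.

    ``proteins``: iterable of (protein_id, family_tag, sequence). An edge
    joins i and j when the better-direction e-value is ≤ threshold; the
    database size n is the total residue count of the input set.
    """
    scheme = scheme or ScoringScheme()
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    items = list(proteins)
    ids = [p[0] for p in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes}")
    g = nx.Graph()
    for pid, fam, seq in items:
        _validate_protein(seq, pid)
        g.add_node(pid, family=fam, length=len(seq))
    db_residues = sum(len(p[2]) for p in items)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            pi, fi, si = items[i]
            pj, fj, sj = items[j]
            hit = local_align(si, sj, scheme, pi, pj)
            if hit.raw_score <= 0:
                continue
            e_fwd = estimate_evalue(hit, db_residues, scheme,
                                    query_residues=len(si))
            e_rev = estimate_evalue(hit, db_residues, scheme,
                                    query_residues=len(sj))
            e = min(e_fwd, e_rev)
            if e <= threshold:
                g.add_edge(pi, pj, e_value=e, raw_score=hit.raw_score,
                           bit_score=hit.bit_score)
    return g


@dataclass
class Cluster:
    cluster_id: str
    member_ids: list
    families_present: frozenset


def cluster_components(g: nx.Graph) -> list[Cluster]:
    """Connected components of the similarity graph as clusters."""
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    out = []
    for i, members in enumerate(comps):
        fams = frozenset(g.nodes[m]["family"] for m in members)
        out.append(Cluster(f"c{i:04d}", members, fams))
    return out


def find_shared_clusters(clusters) -> list[Cluster]:
    """Clusters containing members of both focal families, by cluster id."""
    return sorted((c for c in clusters if {"A", "B"} <= set(c.families_present)),
                  key=lambda c: c.cluster_id)
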