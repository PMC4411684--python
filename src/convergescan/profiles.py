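"""Cluster alignment, position-specific profiles, and taxon-binned search.

Each shared cluster is aligned progressively (UPGMA guide tree over pairwise
alignment distances, profile–profile merging), summarized as a
position-specific scoring matrix (PSSM: pseudocounted column probabilities
turned into log-odds against a background), and searched against a
taxon-labelled protein database — optionally extended with open reading
frames translated from nucleotide contigs in all six frames. Hits are binned
into six taxonomic categories and capped at the top 20 per category, which
keeps the downstream phylogeny tractable without losing any category.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from ._wag import AA_ORDER
from .homology import ScoringScheme, STANDARD_AA
from .msa import MSA, GAP_CHARS

__all__ = [
    "TaxCategory",
    "Profile",
    "BinnedHits",
    "progressive_align",
    "build_profile",
    "translate_orfs",
    "profile_search",
    "bin_by_taxonomy",
]

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class TaxCategory(enum.Enum):
    """The six reference-database bins used for origin assignment."""

    insect_large_dsDNA_virus = "insect_large_dsDNA_virus"
    non_insect_large_dsDNA_virus = "non_insect_large_dsDNA_virus"
    invertebrate = "invertebrate"
    vertebrate = "vertebrate"
    plant = "plant"
    bacteria = "bacteria"


FOCAL_TAGS = {"focal_A", "focal_B"}
# host sequences are insect (invertebrate) by definition here
_TAG_TO_CATEGORY = {c.value: c for c in TaxCategory}
_TAG_TO_CATEGORY["host"] = TaxCategory.invertebrate


# ---------------------------------------------------------------------------
# progressive alignment

def _pairwise_global(a: str, b: str, scheme: ScoringScheme):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.substitution_matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner.score(a, b)


def _profile_columns(msa_rows: dict) -> list:
    keys = list(msa_rows)
    length = len(next(iter(msa_rows.values())))
    return [[msa_rows[k][i] for k in keys] for i in range(length)]


def _col_score(c1, c2, matrix) -> float:
    pairs = [(r1, r2) for r1 in c1 if r1 not in GAP_CHARS
             for r2 in c2 if r2 not in GAP_CHARS]
    if not pairs:
        return 0.0
    return sum(matrix[r1, r2] for r1, r2 in pairs) / len(pairs)


def _merge_profiles(rows1: dict, rows2: dict, scheme: ScoringScheme,
                    gap_cost: float = -4.0) -> dict:
    """Global profile–profile alignment (linear gap cost on columns)."""
    c1, c2 = _profile_columns(rows1), _profile_columns(rows2)
    n, m = len(c1), len(c2)
    mat = scheme.substitution_matrix
    S = np.zeros((n + 1, m + 1))
    S[:, 0] = np.arange(n + 1) * gap_cost
    S[0, :] = np.arange(m + 1) * gap_cost
    ptr = np.zeros((n + 1, m + 1), dtype=int)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = S[i - 1, j - 1] + _col_score(c1[i - 1], c2[j - 1], mat)
            up = S[i - 1, j] + gap_cost
            left = S[i, j - 1] + gap_cost
            best = max(diag, up, left)
            S[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback
    out1, out2 = [], []
    i, j = n, m
    k1, k2 = list(rows1), list(rows2)
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            out1.append(c1[i - 1]); out2.append(c2[j - 1]); i -= 1; j -= 1
        elif p == 1 and i > 0:
            out1.append(c1[i - 1]); out2.append(["-"] * len(k2)); i -= 1
        else:
            out1.append(["-"] * len(k1)); out2.append(c2[j - 1]); j -= 1
    out1.reverse(); out2.reverse()
    keys = k1 + k2
    cols = [a + b for a, b in zip(out1, out2)]
    return {key: "".join(col[r] for col in cols) for r, key in enumerate(keys)}


def progressive_align(sequences: dict, scheme: ScoringScheme | None = None) -> MSA:
    """Progressive multiple alignment with a UPGMA guide tree.

    Pairwise global alignment scores give distances (score deficit relative
    to self-alignment); profiles are merged along the UPGMA join order.
    Ungapping any output row reproduces its input sequence.
    """
    scheme = scheme or ScoringScheme()
    items = dict(sequences)
    if not items:
        raise ValueError("no sequences to align")
    if len(items) == 1:
        warnings.warn("single sequence: returning 1-row alignment")
        return MSA(dict(items))
    keys = list(items)
    n = len(keys)
    selfscore = {k: _pairwise_global(items[k], items[k], scheme) for k in keys}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = _pairwise_global(items[keys[i]], items[keys[j]], scheme)
            d = max(selfscore[keys[i]], selfscore[keys[j]]) - s
            D[i, j] = D[j, i] = max(d, 0.0)
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    profiles = {i: {keys[i]: items[keys[i]]} for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        merged = _merge_profiles(profiles.pop(int(a)), profiles.pop(int(b)),
                                 scheme)
        profiles[n + step] = merged
    (final,) = profiles.values()
    return MSA(final)


# ---------------------------------------------------------------------------
# PSSM

@dataclass
class Profile:
    """Position-specific scoring matrix (log-odds vs background)."""

    log_odds: np.ndarray              # (length, 20)
    background: np.ndarray            # (20,)
    pseudocount_weight: float
    probabilities: np.ndarray = None  # (length, 20)

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def to_tsv(self) -> str:
        lines = [f"#length\t{self.length}",
                 "#background\t" + "\t".join(f"{b:.10g}" for b in self.background)]
        lines.append("pos\t" + "\t".join(AA_ORDER))
        for i in range(self.length):
            lines.append(f"{i}\t" + "\t".join(f"{v:.10g}"
                                              for v in self.log_odds[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Profile":
        lines = [l for l in text.strip().split("\n")]
        bg = np.array([float(x) for x in lines[1].split("\t")[1:]])
        rows = [np.array([float(x) for x in l.split("\t")[1:]])
                for l in lines[3:]]
        return cls(np.vstack(rows), bg, pseudocount_weight=float("nan"))


def build_profile(msa: MSA, pseudocount_weight: float = 1.0,
                  background=None) -> Profile:
    """Column probabilities with background pseudocounts, then log-odds.

    p_col = (counts + w·background) / (n_ungapped + w). Columns that are all
    gaps are dropped with a warning.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    bg = (np.full(20, 0.05) if background is None
          else np.asarray(background, dtype=float))
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must sum to 1")
    probs = []
    dropped = 0
    for i in range(msa.length):
        col = [c for c in msa.column(i).upper() if c not in GAP_CHARS]
        col = [c for c in col if c in _AA_INDEX]
        if not col:
            dropped += 1
            continue
        counts = np.zeros(20)
        for c in col:
            counts[_AA_INDEX[c]] += 1
        probs.append((counts + pseudocount_weight * bg)
                     / (len(col) + pseudocount_weight))
    if dropped:
        warnings.warn(f"dropped {dropped} all-gap column(s)")
    if not probs:
        raise ValueError("no informative columns")
    P = np.vstack(probs)
    with np.errstate(divide="ignore"):
        lo = np.log(P) - np.log(bg)[None, :]
    return Profile(lo, bg, pseudocount_weight, probabilities=P)


# ---------------------------------------------------------------------------
# ORF translation

_STOPS = {"TAA", "TAG", "TGA"}


def translate_orfs(contigs: dict, min_aa: int = 30) -> dict:
    """Six-frame ORF extraction (ATG → stop, standard genetic code).

    ``contigs``: mapping contig id → DNA string (ACGTN). Returns protein
    records keyed ``contig|strand|frame|aa_start-aa_end`` (coordinates in
    codons on that frame). Within a stop-to-stop segment the first ATG
    opens the reading; N-containing codons translate to X.
    """
    out = {}
    for cid, seq in contigs.items():
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{cid}: non-DNA characters {sorted(bad)}")
        for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
            for frame in range(3):
                codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
                i = 0
                while i < len(codons):
                    if codons[i] == "ATG":
                        j = i
                        aa = []
                        while j < len(codons) and codons[j] not in _STOPS:
                            aa.append(str(Seq(codons[j]).translate()))
                            j += 1
                        prot = "".join(aa)
                        if len(prot) >= min_aa:
                            key = f"{cid}|{strand}{frame + 1}|{i}-{j}"
                            out[key] = prot
                        # resume after this reading (segment consumed)
                        i = j + 1
                    else:
                        i += 1
    return out


# ---------------------------------------------------------------------------
# profile search

@dataclass
class ProfileHit:
    hit_id: str
    score: float
    e_value: float


def profile_search(profile: Profile, db: dict,
                   karlin_lambda: float = 1.0, karlin_K: float = 0.1) -> list:
    """Best gapless local profile-to-sequence score for each database entry.

    The PSSM has no insert/delete states, so the local alignment is the
    best-scoring diagonal run (DP with floor 0). Scores are natural
    log-odds, hence λ = 1 in the Karlin–Altschul e-value. Hits are ranked
    by ascending (e-value, id).
    """
    if profile.length == 0:
        raise ValueError("empty profile")
    if not db:
        raise ValueError("empty database")
    db_residues = sum(len(s) for s in db.values())
    hits = []
    lo = profile.log_odds
    for sid in sorted(db):
        seq = db[sid].upper()
        enc = np.array([_AA_INDEX.get(c, -1) for c in seq])
        L = len(enc)
        best = 0.0
        prev = np.zeros(L + 1)
        for i in range(profile.length):
            cur = np.zeros(L + 1)
            scores = np.where(enc >= 0, lo[i][np.clip(enc, 0, 19)], 0.0)
            cur[1:] = np.maximum(prev[:-1] + scores, 0.0)
            best = max(best, cur.max())
            prev = cur
        if profile.length == 1 and L == 1 and enc[0] >= 0:
            best = float(lo[0][enc[0]])  # degenerate case: report the cell
        e = karlin_K * profile.length * db_residues * math.exp(
            -karlin_lambda * best)
        hits.append(ProfileHit(sid, float(best), float(e)))
    hits.sort(key=lambda h: (h.e_value, h.hit_id))
    return hits


# ---------------------------------------------------------------------------
# taxonomic binning

@dataclass
class BinnedHits:
    """Hits per taxonomic category (≤ cap each) plus untrimmed focal hits."""

    by_category: dict = field(default_factory=dict)
    focal: list = field(default_factory=list)
    cap: int = 20


def bin_by_taxonomy(hits, taxmap: dict, cap: int = 20) -> BinnedHits:
    """Assign ranked hits to the six categories, keeping the top ``cap``.

    Every hit id must appear in ``taxmap`` with one of the six category
    names, ``host`` (binned as invertebrate), or ``focal_A``/``focal_B``
    (passed through untrimmed). Lists stay sorted by (e-value, id).
    """
    out = BinnedHits(by_category={c: [] for c in TaxCategory}, cap=cap)
    ordered = sorted(hits, key=lambda h: (h.e_value, h.hit_id))
    for h in ordered:
        if h.hit_id not in taxmap:
            raise KeyError(f"hit id not in taxonomy map: {h.hit_id}")
        tag = taxmap[h.hit_id]
        if tag in FOCAL_TAGS:
            out.focal.append(h)
            continue
        cat = _TAG_TO_CATEGORY.get(tag)
        if cat is None:
            raise KeyError(f"unknown taxonomy tag {tag!r} for {h.hit_id}")
        if len(out.by_category[cat]) < cap:
            out.by_category[cat].append(h)
    return out
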