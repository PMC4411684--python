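"""Origin assignment, convergence calling, and the shared-cluster report.

A shared cluster's putative origin is read off its annotated gene tree: each
maximal clade of a focal family is traced outward to its nearest non-focal
sister leaves (crossing only well-supported edges — weaker edges are
collapsed first), and the origin is the most specific taxonomic label
covering those sisters, through the bundled hierarchy
Lepidoptera ⊂ Insecta ⊂ Bilateria ⊂ Metazoa ⊂ Eukaryote. A tree without any
cellular sequence yields a viral origin. When the two families' clades
disagree, the origins are reported as a compound "A-label/B-label".

Convergence calling distinguishes three histories for a cluster present in
both families: separate, independently rooted clades (convergent
acquisition); one family nested inside the other's clade (a recent
inter-family transfer); and a single clade with one entry point (one ancient
acquisition followed by vertical descent).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .reconcile import as_utree
from .unrooted import UTree

__all__ = [
    "OriginCall",
    "ConvergenceCall",
    "ClusterReportRow",
    "OriginTally",
    "classify_origin",
    "classify_cluster_origin",
    "detect_convergence",
    "tally_origins",
    "read_cluster_table",
    "write_cluster_table",
    "load_reference_table",
]

# taxonomic hierarchy of annotation labels (child -> parent)
TAX_HIERARCHY = {
    "Lepidoptera": "Insecta",
    "Diptera": "Insecta",
    "Insecta": "Bilateria",
    "Vertebrata": "Bilateria",
    "Bilateria": "Metazoa",
    "Metazoa": "Eukaryote",
    "Plantae": "Eukaryote",
    "Unicellular eukaryote": "Eukaryote",
    "Eukaryote": "Cellular",
    "Bacteria": "Cellular",
}

# how hierarchy nodes render as origin labels (closed vocabulary)
_NODE_TO_LABEL = {
    "Lepidoptera": "Insecta (Lepidoptera)",
    "Diptera": "Insecta",
    "Insecta": "Insecta",
    "Vertebrata": "Eukaryote",
    "Bilateria": "Eukaryote",
    "Metazoa": "Eukaryote",
    "Plantae": "Eukaryote",
    "Unicellular eukaryote": "Unicellular eukaryote",
    "Eukaryote": "Eukaryote",
    "Bacteria": "Bacteria",
    "Cellular": "Unknown",
}

FOCAL_TAGS = ("focal_A", "focal_B")


def _ancestors(node: str) -> list:
    out = [node]
    while node in TAX_HIERARCHY:
        node = TAX_HIERARCHY[node]
        out.append(node)
    return out


def _taxon_lca(labels) -> str:
    paths = [list(reversed(_ancestors(l))) for l in set(labels)]
    lca = "Cellular"
    for level in zip(*paths):
        if len(set(level)) == 1:
            lca = level[0]
        else:
            break
    return lca


@dataclass
class OriginCall:
    cluster_id: str
    origin_label: str
    support: float
    rationale: str


@dataclass
class ConvergenceCall:
    cluster_id: str
    independent_acquisitions: int
    families_involved: frozenset
    evidence: str  # separate_clades | recent_inter_family_HGT | single_ancient_acquisition


def _collapse_low_support(ut: UTree, support_min: float) -> UTree:
    """Collapse internal edges with support below the threshold."""
    ut = ut.copy()
    for edge in ut.edges():
        if edge not in ut.edge_data:
            continue
        u, v = tuple(edge)
        if u not in ut.adj or v not in ut.adj:
            continue
        if ut.degree(u) <= 1 or ut.degree(v) <= 1:
            continue
        supp = ut.edge_data[edge].support
        if supp is not None and supp < support_min:
            ut.remove_edge(u, v)
            for m in list(ut.adj[v]):
                d = ut.edge_data[frozenset((v, m))]
                ut.remove_edge(v, m)
                ut.add_edge(u, m, length=d.length, support=d.support)
            del ut.adj[v]
    return ut


def _maximal_pure_sides(ut: UTree, is_member) -> list:
    """Maximal leaf sets hanging off one edge whose leaves all satisfy
    ``is_member``; returns [(leafset, outside_node, inside_node), ...]."""
    sides: dict[frozenset, tuple] = {}
    for edge in ut.edges():
        u, v = tuple(edge)
        for inside, outside in ((u, v), (v, u)):
            leaves = ut.side_leaves(inside, outside)
            if leaves and all(is_member(l) for l in leaves):
                sides.setdefault(leaves, (outside, inside))
    return [(s, o, i) for s, (o, i) in sorted(sides.items(),
                                              key=lambda kv: sorted(kv[0]))
            if not any(s < t for t in sides)]


def classify_origin(tree, annotations: dict, focal: str = "A",
                    support_min: float = 50.0,
                    cluster_id: str = "") -> OriginCall:
    """Putative origin of one focal family's copies in an annotated tree.

    ``annotations`` maps each leaf label to ``focal_A``/``focal_B``, a
    taxonomy label of the bundled hierarchy, or ``Virus``. For each maximal
    focal clade, the nearest non-focal sister leaves decide the label; their
    viral members count only when no cellular sister is present, and a tree
    with no cellular leaves at all is assigned a viral origin.
    """
    ut = as_utree(tree)
    focal_tag = f"focal_{focal}"
    leaves = ut.leaf_labels
    missing = leaves - set(annotations)
    if missing:
        raise ValueError(f"unannotated leaves: {sorted(missing)}")
    if not any(annotations[l] == focal_tag for l in leaves):
        raise ValueError(f"no leaves of focal family {focal}")
    cellular = [l for l in leaves
                if annotations[l] not in FOCAL_TAGS
                and annotations[l] != "Virus"]
    if not cellular:
        return OriginCall(cluster_id, "Virus", 100.0,
                          "no cellular homolog in tree")
    ut = _collapse_low_support(ut, support_min)

    labels = []
    supports = []
    rationales = []
    for clade, out_node, _ in _maximal_pure_sides(
            ut, lambda l: annotations[l] == focal_tag):
        # breadth-first outward walk from the attachment node
        sisters, min_supp = _nearest_nonfocal(ut, out_node, clade,
                                              annotations, focal_tag)
        anns = {annotations[l] for l in sisters}
        cell_anns = anns - {"Virus"} - set(FOCAL_TAGS)
        if cell_anns:
            node = _taxon_lca(cell_anns)
            labels.append(_NODE_TO_LABEL[node])
        else:
            labels.append("Virus")
        supports.append(min_supp)
        rationales.append(f"{sorted(clade)} sister to {sorted(sisters)}")

    uniq = sorted(set(labels))
    if len(uniq) == 1:
        label = uniq[0]
    else:
        cellular_labels = [l for l in uniq if l != "Virus"]
        if not cellular_labels:
            label = "Virus"
        elif len(cellular_labels) == 1:
            label = cellular_labels[0]
        else:
            # conflicting cellular contexts within one family
            back = {v: k for k, v in _NODE_TO_LABEL.items() if v in cellular_labels}
            label = _NODE_TO_LABEL[_taxon_lca(back.values())]
    return OriginCall(cluster_id, label, min(supports) if supports else 100.0,
                      "; ".join(rationales))


def _nearest_nonfocal(ut: UTree, start: int, clade: frozenset,
                      annotations: dict, focal_tag: str):
    """BFS outward from a clade's attachment, returning the first ring of
    non-focal leaves and the minimum support crossed to reach them."""
    from collections import deque
    blocked = {n for n in ut.adj
               if n in ut.label and ut.label[n] in clade}
    q = deque([(start, 100.0)])
    seen = set(blocked) | {start}
    found, best_supp = [], 100.0
    while q:
        node, supp = q.popleft()
        if node in ut.label and len(ut.adj[node]) <= 1:
            if annotations[ut.label[node]] != focal_tag:
                found.append(ut.label[node])
                best_supp = min(best_supp, supp)
            continue
        if found:
            continue
        for m in ut.adj[node]:
            if m in seen:
                continue
            seen.add(m)
            d = ut.edge_data[frozenset((node, m))]
            s = d.support if d.support is not None else 100.0
            if m in ut.label and len(ut.adj[m]) <= 1:
                if annotations[ut.label[m]] != focal_tag:
                    found.append(ut.label[m])
                    best_supp = min(best_supp, min(supp, s))
            else:
                q.append((m, min(supp, s)))
    return found, best_supp


def classify_cluster_origin(tree, annotations: dict,
                            support_min: float = 50.0,
                            cluster_id: str = "") -> OriginCall:
    """Cluster-level origin from the combined focal clades.

    Both families' copies are treated as one focal set: each maximal
    combined clade is traced to its nearest reference sisters (so two
    intermixed viral clades inside an insect clade read as insect origin,
    the pattern of host-derived genes passed between viruses). Distinct
    entry contexts yield a compound label; more than two distinct contexts
    reduce to their common taxonomic ancestor.
    """
    ut = as_utree(tree)
    leaves = ut.leaf_labels
    missing = leaves - set(annotations)
    if missing:
        raise ValueError(f"unannotated leaves: {sorted(missing)}")
    focal = {l for l in leaves if annotations[l] in FOCAL_TAGS}
    if not focal:
        raise ValueError("no focal leaves in tree")
    cellular = [l for l in leaves - focal if annotations[l] != "Virus"]
    if not cellular:
        return OriginCall(cluster_id, "Virus", 100.0,
                          "no cellular homolog in tree")
    ut = _collapse_low_support(ut, support_min)

    labels, supports, rationales = [], [], []
    for clade, out_node, _ in _maximal_pure_sides(
            ut, lambda l: l in focal):
        sisters, min_supp = _nearest_nonfocal_set(ut, out_node, clade, focal)
        anns = {annotations[l] for l in sisters}
        cell_anns = anns - {"Virus"}
        if cell_anns:
            labels.append(_NODE_TO_LABEL[_taxon_lca(cell_anns)])
        else:
            labels.append("Virus")
        supports.append(min_supp)
        rationales.append(f"{sorted(clade)} sister to {sorted(sisters)}")

    uniq = []
    for l in labels:
        if l not in uniq:
            uniq.append(l)
    support = min(supports) if supports else 100.0
    rationale = "; ".join(rationales)
    if len(uniq) == 1:
        return OriginCall(cluster_id, uniq[0], support, rationale)
    if len(uniq) == 2:
        return OriginCall(cluster_id, "/".join(uniq), support, rationale)
    back = {v: k for k, v in _NODE_TO_LABEL.items()}
    nodes = [back.get(l) for l in uniq if back.get(l)]
    label = _NODE_TO_LABEL[_taxon_lca(nodes)] if nodes else "Unknown"
    return OriginCall(cluster_id, label, support, rationale)


def _nearest_nonfocal_set(ut: UTree, start: int, clade: frozenset,
                          focal: set):
    """Like :func:`_nearest_nonfocal` but with an explicit focal leaf set."""
    from collections import deque
    blocked = {n for n in ut.adj
               if n in ut.label and ut.label[n] in clade}
    q = deque([(start, 100.0)])
    seen = set(blocked) | {start}
    found, best_supp = [], 100.0
    while q:
        node, supp = q.popleft()
        if node in ut.label and len(ut.adj[node]) <= 1:
            if ut.label[node] not in focal:
                found.append(ut.label[node])
                best_supp = min(best_supp, supp)
            continue
        if found:
            continue
        for m in ut.adj[node]:
            if m in seen:
                continue
            seen.add(m)
            d = ut.edge_data[frozenset((node, m))]
            s = d.support if d.support is not None else 100.0
            if m in ut.label and len(ut.adj[m]) <= 1:
                if ut.label[m] not in focal:
                    found.append(ut.label[m])
                    best_supp = min(best_supp, min(supp, s))
            else:
                q.append((m, min(supp, s)))
    return found, best_supp


def detect_convergence(tree, annotations: dict, support_min: float = 0.0,
                       cluster_id: str = "") -> ConvergenceCall:
    """Count independent entry points of the two families into a gene tree.

    ``separate_clades``: A and B copies form disjoint maximal focal clades
    (each with its own sister context) — convergent acquisition.
    ``recent_inter_family_HGT``: one family's copies nest inside the other
    family's clade. ``single_ancient_acquisition``: one combined clade whose
    basal split separates the families. Note that because the two families
    share no common ancestor, a single entry point still implies at least
    one (ancient) inter-family exchange after the acquisition.
    """
    ut = as_utree(tree)
    leaves = ut.leaf_labels
    fams = {f for f in ("A", "B")
            if any(annotations.get(l) == f"focal_{f}" for l in leaves)}
    if fams != {"A", "B"}:
        raise ValueError("both focal families must be present")
    ut = _collapse_low_support(ut, support_min)
    focal = {l for l in leaves if annotations[l] in FOCAL_TAGS}

    if focal == leaves:
        # no reference context: a single combined pool; resolved by whether
        # the families are reciprocally monophyletic
        mono = False
        for e in ut.edges():
            u, v = tuple(e)
            s = ut.side_leaves(v, u)
            if s and s != leaves:
                a1 = {annotations[x] for x in s}
                a2 = {annotations[x] for x in leaves - s}
                if len(a1) == 1 and len(a2) == 1 and a1 != a2:
                    mono = True
                    break
        evidence = ("single_ancient_acquisition" if mono
                    else "recent_inter_family_HGT")
        return ConvergenceCall(cluster_id, 1, frozenset(fams), evidence)

    clades = _maximal_pure_sides(ut, lambda l: l in focal)
    n_entries = len(clades)
    mixed = [c for c, _, _ in clades
             if len({annotations[l] for l in c}) == 2]
    if not mixed:
        return ConvergenceCall(cluster_id, n_entries, frozenset(fams),
                               "separate_clades")
    # a combined clade: basal reciprocal monophyly vs nesting
    for cl, out_node, in_node in clades:
        if len({annotations[l] for l in cl}) != 2:
            continue
        basal = [ut.side_leaves(m, in_node) for m in ut.adj[in_node]
                 if m != out_node]
        pure = all(len({annotations[l] for l in part}) == 1
                   for part in basal)
        if not pure:
            return ConvergenceCall(cluster_id, n_entries, frozenset(fams),
                                   "recent_inter_family_HGT")
    evidence = ("single_ancient_acquisition" if n_entries == 1
                else "separate_clades")
    return ConvergenceCall(cluster_id, n_entries, frozenset(fams), evidence)


# ---------------------------------------------------------------------------
# shared-cluster report table

@dataclass
class ClusterReportRow:
    cluster_name: str
    best_cross_family_evalue: str   # kept verbatim for round-tripping
    in_other_large_dsDNA: bool
    putative_origin: str
    figure_ref: str

    @property
    def evalue(self) -> float:
        return float(self.best_cross_family_evalue)


_ORIGIN_RANK = [
    "-",
    "Bacteria",
    "Insecta",
    "Insecta (Lepidoptera)",
    "Insecta (Lepidoptera) & Eukaryote",
    "Bilateria/Insecta (Lepidoptera)",
    "Insecta/Unknown",
    "Eukaryote",
    "Unicellular eukaryote",
    "Unicellular eukaryote (Amoebozoa)",
    "Virus",
    "Unknown",
]

_HEADER = ("cluster_name\tbest_cross_family_evalue\tin_other_large_dsDNA\t"
           "putative_origin\tfigure_ref")


def _rank(origin: str) -> int:
    try:
        return _ORIGIN_RANK.index(origin)
    except ValueError:
        return len(_ORIGIN_RANK)


def write_cluster_table(rows) -> str:
    """Serialize report rows (ordered by origin class, then name)."""
    ordered = sorted(rows, key=lambda r: (_rank(r.putative_origin),
                                          r.cluster_name.casefold()))
    lines = [_HEADER]
    for r in ordered:
        lines.append("\t".join([
            r.cluster_name, r.best_cross_family_evalue,
            "X" if r.in_other_large_dsDNA else "-",
            r.putative_origin, r.figure_ref]))
    return "\n".join(lines) + "\n"


def read_cluster_table(text: str) -> list:
    rows = []
    lines = text.strip().split("\n")
    if lines and lines[0] != _HEADER:
        raise ValueError("unexpected header in cluster table")
    for line in lines[1:]:
        name, ev, other, origin, fig = line.split("\t")
        rows.append(ClusterReportRow(name, ev, other == "X", origin, fig))
    return rows


def load_reference_table() -> list:
    """The bundled 33-row shared-cluster table (the worked example)."""
    text = (importlib.resources.files("convergescan") / "data" / "shared_cluster_table.tsv"
            ).read_text()
    return read_cluster_table(text)


@dataclass
class OriginTally:
    insect: int = 0
    eukaryote_non_metazoan: int = 0
    bacteria: int = 0
    virus: int = 0
    core: int = 0

    @property
    def total_shared(self) -> int:
        return (self.insect + self.eukaryote_non_metazoan + self.bacteria
                + self.virus + self.core)

    @property
    def total_accessory(self) -> int:
        return self.total_shared - self.core


def tally_origins(rows, core_ids=frozenset({"DNA polymerase"})) -> OriginTally:
    """Aggregate report rows into the headline origin classes.

    Any label naming Insecta counts as insect origin; Eukaryote /
    Unicellular eukaryote as non-metazoan eukaryote; Bacteria and Virus as
    themselves. Core genes (by name) are tallied separately. Unknown or
    unrecognized labels raise.
    """
    t = OriginTally()
    for r in rows:
        if r.cluster_name in core_ids:
            t.core += 1
        elif "Insecta" in r.putative_origin:
            t.insect += 1
        elif "eukaryote" in r.putative_origin or "Eukaryote" in r.putative_origin:
            t.eukaryote_non_metazoan += 1
        elif "Bacteria" in r.putative_origin:
            t.bacteria += 1
        elif "Virus" in r.putative_origin:
            t.virus += 1
        else:
            raise ValueError(
                f"cannot aggregate origin {r.putative_origin!r} "
                f"for {r.cluster_name!r}")
    return t
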