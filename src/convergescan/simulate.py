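"""Synthetic evolution of accessory genes in two unrelated virus families.

The generator provides every downstream stage with ground truth. It draws
three independent ultrametric phylogenies — an insect host clade and two
unrelated virus families A and B — assigns each virus a host range of 1–3
hosts, and then simulates gene families on top: a family originates in an
external source (the host clade, a bacterial outgroup, an unrelated-virus
outgroup) or natively in one virus family, is gained by viral lineages,
lost, and horizontally transferred between contemporaneous viral lineages
whose host ranges intersect (the mixed-infection contact model). Protein
sequences then evolve along the implied gene genealogy under WAG with
discrete-gamma rate variation; no insertions or deletions are simulated, so
sequences of one family stay aligned by construction.

All randomness derives from a single seed through named sub-streams, so any
stage can be replayed independently and reproduced byte for byte.
"""

from __future__ import annotations

import io
import json
import math
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from ._wag import AA_ORDER
from .phylo import SubstModel

__all__ = [
    "SimConfig",
    "SpeciesTreeSet",
    "EventRecord",
    "GeneFamilyHistory",
    "EventLog",
    "simulate_species_trees",
    "simulate_gene_histories",
    "evolve_sequences",
    "replay_presence",
    "simulate_dataset",
]

SOURCE_LEAF_COUNT = 3  # leaves of the bacterial / unrelated-virus outgroups


@dataclass
class SimConfig:
    """Parameters of the synthetic-evolution generator.

    Rates are per gene per unit branch time; branch time is measured in
    expected substitutions per site (trees are scaled to ``tree_height``
    root-to-tip), so a loss_rate of 0.2 means one expected loss per five
    substitutions per site of lineage history.
    """

    n_hosts: int = 6
    n_family_A: int = 6
    n_family_B: int = 6
    birth_rate: float = 1.0
    death_rate: float = 0.2
    gain_rate: float = 0.25
    loss_rate: float = 0.1
    hgt_rate: float = 0.15
    seq_length: int = 300
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    tree_height: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("birth_rate", "death_rate", "gain_rate", "loss_rate",
                     "hgt_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_rate_categories < 1:
            raise ValueError("n_rate_categories must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.tree_height <= 0:
            raise ValueError("tree_height must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# species trees

@dataclass
class _Branch:
    branch_id: str        # label of the node at the tipward end
    parent_id: str | None
    t_start: float        # age of the rootward end (root = 0)
    t_end: float          # age of the tipward end
    children: list = field(default_factory=list)
    is_leaf: bool = False
    hosts: frozenset = frozenset()


class BranchTable:
    """Flat branch view of a rooted ultrametric tree, indexed by node label."""

    def __init__(self, tree: dendropy.Tree, host_of_leaf=None):
        self.branches: dict[str, _Branch] = {}
        self.root_id: str | None = None
        depths = {}
        for nd in tree.preorder_node_iter():
            d = 0.0 if nd.parent_node is None else (
                depths[id(nd.parent_node)] + (nd.edge.length or 0.0))
            depths[id(nd)] = d
            label = nd.taxon.label if nd.taxon else nd.label
            parent = None
            if nd.parent_node is not None:
                p = nd.parent_node
                parent = p.taxon.label if p.taxon else p.label
            else:
                self.root_id = label
            br = _Branch(
                branch_id=label, parent_id=parent,
                t_start=depths[id(nd.parent_node)] if nd.parent_node else 0.0,
                t_end=d, is_leaf=nd.is_leaf())
            self.branches[label] = br
            if parent is not None:
                self.branches[parent].children.append(label)
        # host ranges: union over descendant leaves
        if host_of_leaf is not None:
            for bid in self._postorder():
                br = self.branches[bid]
                if br.is_leaf:
                    br.hosts = frozenset(host_of_leaf.get(bid, ()))
                else:
                    br.hosts = frozenset().union(
                        *(self.branches[c].hosts for c in br.children))

    def _postorder(self):
        out, stack = [], [self.root_id]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.branches[n].children)
        return reversed(out)

    @property
    def total_length(self) -> float:
        return sum(b.t_end - b.t_start for b in self.branches.values())

    def alive_at(self, t: float):
        return [b for b in self.branches.values()
                if b.t_start < t <= b.t_end]

    def leaves_below(self, bid: str):
        out, stack = [], [bid]
        while stack:
            n = stack.pop()
            br = self.branches[n]
            if br.is_leaf:
                out.append(n)
            stack.extend(br.children)
        return sorted(out)


@dataclass
class SpeciesTreeSet:
    """Host clade plus the two unrelated virus family trees."""

    host_tree: dendropy.Tree
    family_A_tree: dendropy.Tree
    family_B_tree: dendropy.Tree
    host_range_map: dict[str, frozenset]
    height: float

    def tables(self) -> dict[str, BranchTable]:
        hosts_own = {lf.taxon.label: {lf.taxon.label}
                     for lf in self.host_tree.leaf_node_iter()}
        return {
            "host": BranchTable(self.host_tree, hosts_own),
            "A": BranchTable(self.family_A_tree, self.host_range_map),
            "B": BranchTable(self.family_B_tree, self.host_range_map),
        }

    def newicks(self) -> dict[str, str]:
        return {k: t.as_string(schema="newick").strip()
                for k, t in (("host", self.host_tree),
                             ("A", self.family_A_tree),
                             ("B", self.family_B_tree))}


def _bd_tree(n: int, prefix: str, birth: float, death: float,
             height: float, rng: random.Random) -> dendropy.Tree:
    if n < 2:
        raise ValueError("each tree needs at least 2 leaves")
    from dendropy.model import birthdeath
    tree = birthdeath.birth_death_tree(
        birth, death, num_extant_tips=n, rng=rng,
        repeat_until_success=True)
    tree.purge_taxon_namespace()
    # the process stops the instant the n-th tip is born, leaving the
    # newest tips with zero-length pendant edges; extend all (extant,
    # contemporaneous) tips by the waiting time to the next event
    extra = rng.expovariate(n * (birth + death))
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = 0.0
    # scale to the requested root-to-tip height
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    if depth > 0:
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * height / depth
    # deterministic labels: leaves in ladderized order, internals postorder
    tree.ladderize()
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        lf.taxon.label = f"{prefix}{i}"
    j = 0
    for nd in tree.postorder_node_iter():
        if not nd.is_leaf():
            j += 1
            nd.label = f"{prefix}_n{j}"
    return tree


def simulate_species_trees(config: SimConfig) -> SpeciesTreeSet:
    """Three independent birth–death trees plus viral host ranges.

    Each tree is conditioned on its requested extant leaf count and scaled
    to ``config.tree_height``; each viral leaf is assigned 1–3 uniformly
    chosen host leaves. Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(4)
    seeds = [int(k.generate_state(1)[0] % (2**31)) for k in keys]
    host = _bd_tree(config.n_hosts, "H", config.birth_rate, config.death_rate,
                    config.tree_height, random.Random(seeds[0]))
    fam_a = _bd_tree(config.n_family_A, "A", config.birth_rate,
                     config.death_rate, config.tree_height,
                     random.Random(seeds[1]))
    fam_b = _bd_tree(config.n_family_B, "B", config.birth_rate,
                     config.death_rate, config.tree_height,
                     random.Random(seeds[2]))
    rng = np.random.default_rng(keys[3])
    host_leaves = [lf.taxon.label for lf in host.leaf_node_iter()]
    host_range = {}
    for tree in (fam_a, fam_b):
        for lf in tree.leaf_node_iter():
            k = int(rng.integers(1, min(3, len(host_leaves)) + 1))
            chosen = rng.choice(len(host_leaves), size=k, replace=False)
            host_range[lf.taxon.label] = frozenset(host_leaves[i] for i in chosen)
    return SpeciesTreeSet(host, fam_a, fam_b, host_range, config.tree_height)


# ---------------------------------------------------------------------------
# gene histories

@dataclass
class EventRecord:
    kind: str            # gain | loss | transfer
    time: float
    donor_branch: str    # source lineage for gains/transfers; "" for losses
    recipient_branch: str


@dataclass
class GeneFamilyHistory:
    family_id: str
    origin_category: str  # host | bacteria | other_virus | family_A_native | family_B_native
    events: list = field(default_factory=list)

    def transfer_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "transfer")

    def cross_family_transfers(self):
        out = []
        for e in self.events:
            if e.kind != "transfer":
                continue
            if _tree_of_branch(e.donor_branch) != _tree_of_branch(e.recipient_branch):
                out.append(e)
        return out


def _tree_of_branch(bid: str) -> str:
    if bid.startswith(("BACT", "OVIR")):
        return "source"
    if bid.startswith("A"):
        return "A"
    if bid.startswith("B"):
        return "B"
    if bid.startswith("H"):
        return "host"
    return "source"


@dataclass
class EventLog:
    histories: list = field(default_factory=list)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("family_id\torigin\tkind\ttime\tdonor\trecipient\n")
        for h in self.histories:
            for e in h.events:
                buf.write(f"{h.family_id}\t{h.origin_category}\t{e.kind}\t"
                          f"{e.time:.12g}\t{e.donor_branch}\t{e.recipient_branch}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "EventLog":
        histories: dict[str, GeneFamilyHistory] = {}
        lines = text.strip().split("\n")[1:]
        for line in lines:
            fam, origin, kind, t, donor, recipient = (line.split("\t") + [""])[:6]
            h = histories.setdefault(fam, GeneFamilyHistory(fam, origin))
            h.events.append(EventRecord(kind, float(t), donor, recipient))
        return cls(list(histories.values()))

    def to_json(self) -> str:
        return json.dumps([{
            "family_id": h.family_id,
            "origin_category": h.origin_category,
            "events": [asdict(e) for e in h.events],
        } for h in self.histories], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        return cls([GeneFamilyHistory(
            d["family_id"], d["origin_category"],
            [EventRecord(**e) for e in d["events"]])
            for d in json.loads(text)])


_ORIGIN_CHOICES = ("host", "bacteria", "other_virus",
                   "family_A_native", "family_B_native")
_ORIGIN_WEIGHTS = (0.4, 0.15, 0.15, 0.15, 0.15)


def _source_table(origin: str, trees: SpeciesTreeSet,
                  tables: dict) -> BranchTable | None:
    """Branch table of the external source carrying the gene, if any."""
    if origin == "host":
        return tables["host"]
    if origin in ("bacteria", "other_virus"):
        prefix = "BACT" if origin == "bacteria" else "OVIR"
        h = trees.height
        newick = "(" + ",".join(
            f"{prefix}{i}:{h}" for i in range(1, SOURCE_LEAF_COUNT + 1)) + ")root;"
        t = dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=False)
        for nd in t.preorder_node_iter():
            if not nd.is_leaf():
                nd.label = f"{prefix}_root"
        return BranchTable(t)
    return None


def simulate_gene_histories(trees: SpeciesTreeSet, config: SimConfig,
                            n_families: int, origins=None) -> EventLog:
    """Simulate gain/loss/transfer histories for ``n_families`` gene families.

    Each family originates in an external source (host clade, bacterial or
    unrelated-virus outgroup) or natively at one family's root. External
    families enter the viral trees through at least one gain (extra gains
    are Poisson with rate ``gain_rate`` per unit total viral branch length,
    modelling convergent acquisition); on viral branches the gene is then
    lost at ``loss_rate`` and transferred at ``hgt_rate`` to contemporaneous
    viral branches with intersecting host ranges that do not already carry
    it. Events are returned time-ordered per family.
    """
    tables = trees.tables()
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,)))
    histories = []
    viral = {**{b.branch_id: ("A", b) for b in tables["A"].branches.values()},
             **{b.branch_id: ("B", b) for b in tables["B"].branches.values()}}
    total_viral_len = tables["A"].total_length + tables["B"].total_length

    for fi in range(n_families):
        if origins is not None:
            origin = origins[fi % len(origins)]
        else:
            origin = rng.choice(_ORIGIN_CHOICES, p=_ORIGIN_WEIGHTS)
        fam = GeneFamilyHistory(f"fam{fi:03d}", str(origin))
        events: list[EventRecord] = []

        # --- gains ---------------------------------------------------
        gains: list[tuple[float, str, str]] = []  # (time, source, recipient)
        if fam.origin_category.endswith("_native"):
            key = "A" if "A_" in fam.origin_category else "B"
            root = tables[key].root_id
            gains.append((0.0, f"native:{key}", root))
        else:
            src = _source_table(fam.origin_category, trees, tables)
            n_gain = 1 + rng.poisson(config.gain_rate * total_viral_len)
            branch_ids = sorted(viral)
            weights = np.array([viral[b][1].t_end - viral[b][1].t_start
                                for b in branch_ids])
            for _ in range(n_gain):
                b = branch_ids[int(rng.choice(len(branch_ids),
                                              p=weights / weights.sum()))]
                br = viral[b][1]
                t = float(rng.uniform(br.t_start, br.t_end))
                # source lineage alive at the gain time
                alive = sorted(s.branch_id for s in src.alive_at(t)) or \
                    [src.root_id]
                donor = alive[int(rng.integers(len(alive)))]
                gains.append((t, donor, b))

        # --- loss / transfer processes on viral lineages ---------------
        # chronological event queue; `open_seg` tracks branches currently
        # carrying the gene, so candidate filters see a consistent present
        import heapq
        open_seg: dict[str, float] = {}
        rate = config.loss_rate + config.hgt_rate
        counter = 0
        queue: list = []

        def push(kind: str, t: float, bid: str, donor: str = ""):
            nonlocal counter
            counter += 1
            heapq.heappush(queue, (t, counter, kind, bid, donor))

        def schedule_next(bid: str, t: float):
            """Sample the next loss/transfer on an open segment after t."""
            br = viral[bid][1]
            dt = float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf
            if t + dt >= br.t_end:
                push("segend", br.t_end, bid)
            else:
                push("event", t + dt, bid)

        for t, donor, b in sorted(gains):
            push("start", t, b, donor)

        while queue:
            t, _, kind, bid, donor = heapq.heappop(queue)
            br = viral[bid][1]
            if kind == "start":
                if bid in open_seg:
                    continue  # already carries the gene; gain is a no-op
                open_seg[bid] = t
                events.append(EventRecord("gain", t, donor, bid))
                schedule_next(bid, t)
            elif kind == "segend":
                if bid not in open_seg:
                    continue
                del open_seg[bid]
                if not br.is_leaf:
                    for c in br.children:
                        if c not in open_seg:
                            open_seg[c] = t
                            schedule_next(c, t)
            elif kind == "event":
                if bid not in open_seg:
                    continue
                if rng.random() < (config.loss_rate / rate if rate > 0 else 0):
                    del open_seg[bid]
                    events.append(EventRecord("loss", t, "", bid))
                    continue
                # transfer to a contemporaneous, host-sharing non-carrier
                candidates = [
                    other for other, (_k, obr) in viral.items()
                    if other != bid and obr.t_start < t <= obr.t_end
                    and other not in open_seg and (br.hosts & obr.hosts)]
                if candidates:
                    recip = sorted(candidates)[int(rng.integers(len(candidates)))]
                    events.append(EventRecord("transfer", t, bid, recip))
                    open_seg[recip] = t
                    schedule_next(recip, t)
                schedule_next(bid, t)

        events.sort(key=lambda e: (e.time, e.kind, e.recipient_branch))
        fam.events = events
        histories.append(fam)
    return EventLog(histories)


def replay_presence(history: GeneFamilyHistory, trees: SpeciesTreeSet):
    """Re-derive presence from the event list alone (independent replay).

    Returns (leaf_carriers, presence_intervals). Raises if the log is
    internally inconsistent (loss of an absent gene, transfer from a
    non-carrying donor).
    """
    import heapq
    tables = trees.tables()
    branch_of = {}
    for key in ("A", "B"):
        for b in tables[key].branches.values():
            branch_of[b.branch_id] = b

    # chronological sweep mirroring the generative process: presence opens
    # at gains/transfers, closes at losses, and flows into child branches
    open_seg: dict[str, float] = {}
    intervals: dict[str, list] = {}
    leaf_carriers: list[str] = []
    counter = 0
    heap: list = []
    PRIO = {"start": 0, "loss": 1, "end": 2}

    def push(kind, t, bid, donor=""):
        nonlocal counter
        counter += 1
        heapq.heappush(heap, (t, PRIO[kind], counter, kind, bid, donor))

    def open_branch(bid, t):
        open_seg[bid] = t
        br = branch_of.get(bid)
        if br is not None:
            push("end", br.t_end, bid)

    for e in history.events:
        if e.kind in ("gain", "transfer"):
            push("start", e.time, e.recipient_branch, e.donor_branch)
        else:
            push("loss", e.time, e.recipient_branch)

    while heap:
        t, _, _, kind, bid, donor = heapq.heappop(heap)
        if kind == "start":
            if donor in branch_of and donor not in open_seg:
                raise ValueError(
                    f"transfer from non-carrying donor {donor}")
            if bid in open_seg:
                raise ValueError(f"gain into branch already carrying {bid}")
            open_branch(bid, t)
        elif kind == "loss":
            if bid not in open_seg:
                raise ValueError(f"loss on absent gene {bid}")
            intervals.setdefault(bid, []).append((open_seg.pop(bid), t))
        elif kind == "end":
            if bid not in open_seg:
                continue  # lost earlier on this branch
            intervals.setdefault(bid, []).append((open_seg.pop(bid), t))
            br = branch_of.get(bid)
            if br is None:
                continue
            if br.is_leaf:
                leaf_carriers.append(bid)
            else:
                for c in br.children:
                    open_branch(c, t)
    return sorted(leaf_carriers), intervals


# ---------------------------------------------------------------------------
# sequence evolution

class _GeneNode:
    __slots__ = ("children", "length", "label")

    def __init__(self, length=0.0, label=None):
        self.children = []
        self.length = length
        self.label = label


def build_genealogy(history: GeneFamilyHistory, trees: SpeciesTreeSet):
    """Gene genealogy implied by a history: nodes at gains, transfers,
    speciations; leaves labelled by carrier species (source and viral)."""
    tables = trees.tables()
    src = _source_table(history.origin_category, trees, tables)
    branch_of = {}
    for key in ("A", "B"):
        for b in tables[key].branches.values():
            branch_of[b.branch_id] = b
    if src is not None:
        for b in src.branches.values():
            branch_of[b.branch_id] = b

    # events grouped by the branch they happen on (donor side for
    # transfers/gains: the new lineage hangs off the donor's lineage)
    out_events: dict[str, list[tuple[float, str]]] = {}
    losses: dict[str, list[float]] = {}
    for e in history.events:
        if e.kind == "loss":
            losses.setdefault(e.recipient_branch, []).append(e.time)
        elif e.kind == "transfer":
            out_events.setdefault(e.donor_branch, []).append(
                (e.time, e.recipient_branch))
        elif e.kind == "gain" and src is not None:
            out_events.setdefault(e.donor_branch, []).append(
                (e.time, e.recipient_branch))

    def descend(bid: str, t: float) -> _GeneNode | None:
        """Gene lineage on branch ``bid`` from time ``t`` onward."""
        br = branch_of[bid]
        pending = sorted([(tt, r) for tt, r in out_events.get(bid, [])
                          if tt >= t])
        loss_times = sorted([lt for lt in losses.get(bid, []) if lt >= t])
        cut = loss_times[0] if loss_times else None
        node_time = t
        head = _GeneNode()
        cursor = head
        for tt, recip in pending:
            if cut is not None and tt > cut:
                break
            side = descend(recip, tt)
            if side is None:
                continue
            mid = _GeneNode(length=tt - node_time)
            mid.children = [side]
            cursor.children.append(mid)
            cursor = mid
            node_time = tt
        if cut is not None:
            tail = None
        elif br.is_leaf:
            tail = _GeneNode(length=br.t_end - node_time, label=bid)
        else:
            kids = [descend(c, br.t_end) for c in br.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                tail = None
            elif len(kids) == 1:
                kids[0].length += br.t_end - node_time
                tail = kids[0]
            else:
                tail = _GeneNode(length=br.t_end - node_time)
                tail.children = kids
        if tail is not None:
            cursor.children.append(tail)
        # simplify chain: head is a zero-length pass-through
        return _collapse(head)

    def _collapse(node: _GeneNode) -> _GeneNode | None:
        while node.label is None and len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            node = child
        if node.label is None and not node.children:
            return None
        node.children = [c for c in
                         (_collapse(ch) for ch in node.children) if c]
        if node.label is None and not node.children:
            return None
        if node.label is None and len(node.children) == 1:
            c = node.children[0]
            c.length += node.length
            return c
        return node

    if history.origin_category.endswith("_native"):
        gain = next(e for e in history.events if e.kind == "gain")
        return descend(gain.recipient_branch, gain.time)
    # external origin: gene is ancestrally present across the source tree
    root_id = src.root_id
    return descend(root_id, 0.0)


def genealogy_newick(node: _GeneNode) -> str:
    def rec(n):
        if not n.children:
            return f"{n.label}:{n.length:.6g}"
        return "(" + ",".join(rec(c) for c in n.children) + f"):{n.length:.6g}"
    return rec(node) + ";" if node else ";"


def evolve_sequences(history: GeneFamilyHistory, trees: SpeciesTreeSet,
                     config: SimConfig) -> dict[str, str]:
    """Evolve one protein per carrier leaf along the gene genealogy.

    Root sequence is drawn from the WAG stationary distribution; each site
    is assigned one of the discrete-gamma rate categories; substitutions
    follow P(r·t) per branch. A transferred copy continues from the donor
    sequence at the transfer time. Deterministic given the config seed and
    the family id (independent of the history-generation stream).
    """
    import zlib
    model = SubstModel(gamma_shape=config.gamma_shape,
                       n_categories=config.n_rate_categories)
    fam_key = zlib.crc32(history.family_id.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2, fam_key)))
    L = config.seq_length
    root_seq = rng.choice(20, size=L, p=model.freqs)
    cats = rng.integers(0, model.n_categories, size=L)
    rates = model.rates[cats]

    genealogy = build_genealogy(history, trees)
    out: dict[str, str] = {}
    if genealogy is None:
        return out

    def walk(node: _GeneNode, seq: np.ndarray) -> None:
        if node.length > 0:
            child = seq.copy()
            for k in range(model.n_categories):
                sites = np.where(cats == k)[0]
                if sites.size == 0:
                    continue
                P = model.transition(model.rates[k] * node.length)
                C = P.cumsum(axis=1)
                u = rng.random(sites.size)
                child[sites] = (C[seq[sites]] < u[:, None]).sum(axis=1)
            seq = child
        if node.label is not None:
            out[node.label] = "".join(AA_ORDER[i] for i in seq)
        for c in node.children:
            walk(c, seq)

    walk(genealogy, root_seq)
    return out


# ---------------------------------------------------------------------------
# convenience: full dataset

@dataclass
class SimDataset:
    config: SimConfig
    trees: SpeciesTreeSet
    event_log: EventLog
    sequences: dict  # family_id -> {leaf_label: protein}

    def viral_proteins(self):
        """(protein_id, family_tag, taxon, seq) for all focal-family copies."""
        out = []
        for fam_id, seqs in self.sequences.items():
            for leaf, seq in sorted(seqs.items()):
                tag = _tree_of_branch(leaf)
                if tag in ("A", "B"):
                    out.append((f"{fam_id}.{leaf}", tag, leaf, seq))
        return out

    def reference_proteins(self):
        """(protein_id, taxon, seq) for host/bacterial/other-virus copies."""
        out = []
        for fam_id, seqs in self.sequences.items():
            for leaf, seq in sorted(seqs.items()):
                if _tree_of_branch(leaf) in ("host", "source"):
                    out.append((f"{fam_id}.{leaf}", leaf, seq))
        return out

    def taxonomy_of_reference(self) -> dict[str, str]:
        """Reference taxon -> taxonomy label used for origin calling."""
        tax = {}
        for lf in self.trees.host_tree.leaf_node_iter():
            tax[lf.taxon.label] = "Lepidoptera"
        for i in range(1, SOURCE_LEAF_COUNT + 1):
            tax[f"BACT{i}"] = "Bacteria"
            tax[f"OVIR{i}"] = "Virus"
        return tax


def simulate_dataset(config: SimConfig, n_families: int,
                     origins=None) -> SimDataset:
    """Trees + histories + sequences in one call (single-seed pipeline)."""
    trees = simulate_species_trees(config)
    log = simulate_gene_histories(trees, config, n_families, origins=origins)
    seqs = {h.family_id: evolve_sequences(h, trees, config)
            for h in log.histories}
    return SimDataset(config, trees, log, seqs)
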