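"""Ground-truth simulators for every input class the pipeline consumes.

Each generator is deterministic under an explicit seed and returns, next to
the simulated data, the truth needed to verify downstream inference:
gene-family simulations carry a replayable event log, genome layouts carry
their island coordinates, growth curves carry their planted parameters.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .treeio import DatedTree, Tree, as_dated

NUCS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# species trees


def sim_species_tree(
    n_leaves: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    normalize_height: bool = True,
    max_retries: int = 100,
) -> DatedTree:
    """Constant-rate birth-death tree conditioned on ``n_leaves`` extant tips.

    Ultrametric by construction; the stem edge above the root is removed.
    With ``normalize_height`` the root-to-tip span is rescaled to 1 so that
    per-unit-time event rates are comparable across replicates.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if not birth > death >= 0:
        raise ValueError("require birth > death >= 0")
    rng = random.Random(seed)
    last_exc: Exception | None = None
    for _ in range(max_retries):
        try:
            dtree = birthdeath.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_leaves,
                rng=rng,
            )
            break
        except Exception as exc:  # extinction before reaching n
            last_exc = exc
    else:
        raise RuntimeError(f"birth-death conditioning failed: {last_exc}")
    dtree.seed_node.edge.length = None
    # the conditioning stops at the nth birth, leaving the last speciation at
    # the present; extend every tip by the waiting time to the next event so
    # terminal branches have positive length
    extra = rng.expovariate(n_leaves * (birth + death))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree = Tree(dtree)
    if normalize_height:
        h = tree.height()
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= h
    return as_dated(Tree(dtree), tolerance=1e-9)


# ---------------------------------------------------------------------------
# gene families under duplication / transfer / loss / acquisition


@dataclass(frozen=True)
class Event:
    kind: str  # duplication | transfer | loss | acquisition
    time: float
    branch: str  # host (donor for transfers) species branch id
    recipient: str | None = None


@dataclass
class EventLog:
    """Chronological true events plus final per-species copy numbers."""

    events: list[Event] = field(default_factory=list)
    final_counts: dict[str, int] = field(default_factory=dict)
    root_copies: int = 1

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)


def branch_ids(species: DatedTree) -> dict[dendropy.Node, str]:
    """Deterministic species-branch identifiers (leaf label or preorder Nk)."""
    ids: dict[dendropy.Node, str] = {}
    k = 0
    for node in species.d.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"N{k}"
            k += 1
    return ids


class _GNode:
    __slots__ = ("time", "branch", "children", "alive", "label")

    def __init__(self, time: float, branch) -> None:
        self.time = time
        self.branch = branch  # species node whose subtending edge hosts us
        self.children: list[_GNode] = []
        self.alive = False
        self.label: str | None = None


def sim_gene_family(
    species: DatedTree,
    dup_rate: float = 0.1,
    transfer_rate: float = 0.1,
    loss_rate: float = 0.05,
    acquisition_rate: float = 0.0,
    seed: int = 0,
    root_copies: int = 1,
) -> tuple[list[Tree], EventLog]:
    """Gillespie simulation of a gene family down a dated species tree.

    Each extant gene copy duplicates, is lost, or donates a transferred
    copy to a uniformly chosen contemporaneous other branch; external
    acquisitions arrive as a Poisson process and seed new copies on a
    uniform alive branch. At each speciation every copy on the splitting
    branch is inherited by both daughters.

    Returns a gene-tree *forest* (one rooted tree per origin with extant
    descendants; branch lengths in time units) and the complete event log.
    A family extinct before the present yields an empty forest.
    """
    for r in (dup_rate, transfer_rate, loss_rate, acquisition_rate):
        if r < 0:
            raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    bid = branch_ids(species)
    times = sorted({species.times[n] for n in species.d.preorder_node_iter()})
    tip_time = species.tip_time
    # species nodes grouped by their (end) time
    by_time: dict[float, list[dendropy.Node]] = {}
    for node in species.d.preorder_node_iter():
        by_time.setdefault(species.times[node], []).append(node)

    log = EventLog(root_copies=root_copies)
    roots: list[_GNode] = []
    # state: list of open lineages as (species branch node, gene node)
    active: list[tuple[dendropy.Node, _GNode]] = []
    for _ in range(root_copies):
        g = _GNode(0.0, species.root)
        roots.append(g)
        # root copy immediately inherits into both root children
        active.append((species.root, g))

    per_copy = dup_rate + transfer_rate + loss_rate

    t_prev = times[0]  # == 0 at the root
    for t_next in times[1:]:
        # branches alive strictly within (t_prev, t_next)
        alive_branches = [
            n
            for n in species.d.preorder_node_iter()
            if n.parent_node is not None
            and species.times[n.parent_node] <= t_prev
            and species.times[n] >= t_next
        ]
        # lineages sitting on the root stem descend through the root split
        new_active = []
        for br, g in active:
            if species.times[br] <= t_prev and not br.is_leaf():
                g.time = t_prev  # node becomes the speciation event
                for child in br.child_nodes():
                    cg = _GNode(t_prev, child)
                    g.children.append(cg)
                    new_active.append((child, cg))
            else:
                new_active.append((br, g))
        active = new_active

        t = t_prev
        while active or acquisition_rate > 0:
            total = per_copy * len(active) + acquisition_rate
            if total <= 0:
                break
            t = t + rng.exponential(1.0 / total)
            if t >= t_next:
                break
            u = rng.random() * total
            if u < acquisition_rate:
                br = alive_branches[rng.integers(len(alive_branches))]
                g = _GNode(t, br)
                roots.append(g)
                active.append((br, g))
                log.events.append(Event("acquisition", t, bid[br]))
                continue
            idx = int((u - acquisition_rate) // per_copy)
            idx = min(idx, len(active) - 1)
            br, g = active.pop(idx)
            kind_draw = rng.random() * per_copy
            if kind_draw < loss_rate:
                log.events.append(Event("loss", t, bid[br]))
            elif kind_draw < loss_rate + dup_rate:
                c1, c2 = _GNode(t, br), _GNode(t, br)
                g.time = t  # node becomes the duplication event
                g.children = [c1, c2]
                active.append((br, c1))
                active.append((br, c2))
                log.events.append(Event("duplication", t, bid[br]))
            else:
                others = [b for b in alive_branches if b is not br]
                if not others:
                    active.append((br, g))
                    continue
                rec = others[rng.integers(len(others))]
                c_stay, c_jump = _GNode(t, br), _GNode(t, rec)
                g.time = t  # node becomes the transfer event
                g.children = [c_stay, c_jump]
                active.append((br, c_stay))
                active.append((rec, c_jump))
                log.events.append(Event("transfer", t, bid[br], bid[rec]))
        # boundary: speciations (or tips) at t_next; cascade in case a
        # daughter branch itself ends at the same instant
        stack = active
        new_active = []
        while stack:
            br, g = stack.pop()
            if species.times[br] > t_next:
                new_active.append((br, g))
            elif br.is_leaf():
                g.alive = True
                g.time = tip_time
                new_active.append((br, g))  # keep; loop ends at tip time
            else:
                g.time = t_next  # node becomes the speciation event
                for child in br.child_nodes():
                    cg = _GNode(t_next, child)
                    g.children.append(cg)
                    stack.append((child, cg))
        active = new_active
        t_prev = t_next

    # label extant copies and tally final counts
    counts: dict[str, int] = {lb: 0 for lb in species.leaf_labels()}
    for br, g in active:
        if g.alive:
            sp = bid[br]
            counts[sp] += 1
            g.label = f"{sp}|g{counts[sp]}"
    log.final_counts = counts

    forest = [_to_tree(r) for r in roots]
    forest = [t for t in forest if t is not None]
    return forest, log


def _to_tree(groot: _GNode) -> Tree | None:
    """Prune dead lineages, suppress unifurcations, emit a dendropy tree."""

    def prune(g: _GNode) -> _GNode | None:
        kids = [prune(c) for c in g.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return g if g.alive else None
        if len(kids) == 1:
            return kids[0]
        g.children = kids
        return g

    top = prune(groot)
    if top is None:
        return None
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(g: _GNode, parent_time: float) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = max(g.time - parent_time, 0.0)
        if not g.children:
            node.taxon = taxa.new_taxon(g.label)
        for c in g.children:
            node.add_child(build(c, g.time))
        return node

    root_node = build(top, top.time)
    dtree.seed_node = root_node
    dtree.seed_node.edge.length = None
    return Tree(dtree)


def replay_event_log(species: DatedTree, log: EventLog) -> dict[str, int]:
    """Recompute final per-species copy numbers from the event log alone."""
    bid = branch_ids(species)
    # chronological walk: merge events with speciation boundaries
    boundaries = sorted(
        ((species.times[n], i, n)
         for i, n in enumerate(species.d.preorder_node_iter())
         if not n.is_leaf()),
        key=lambda x: (x[0], x[1]),
    )
    events = sorted(log.events, key=lambda e: e.time)
    counts = {b: 0 for b in bid.values()}
    counts[bid[species.root]] = log.root_copies
    ei = 0
    for t_b, _, node in boundaries:
        while ei < len(events) and events[ei].time <= t_b:
            e = events[ei]
            ei += 1
            if e.kind == "loss":
                counts[e.branch] -= 1
            elif e.kind in ("duplication",):
                counts[e.branch] += 1
            elif e.kind == "acquisition":
                counts[e.branch] += 1
            elif e.kind == "transfer":
                counts[e.recipient] += 1
        b = bid[node]
        for child in node.child_nodes():
            counts[bid[child]] += counts[b]
        counts[b] = 0
    while ei < len(events):
        e = events[ei]
        ei += 1
        if e.kind == "loss":
            counts[e.branch] -= 1
        elif e.kind in ("duplication", "acquisition"):
            counts[e.branch] += 1
        elif e.kind == "transfer":
            counts[e.recipient] += 1
    return {lb: counts[lb] for lb in species.leaf_labels()}


def sim_two_origin_family(
    species: DatedTree,
    seed: int = 0,
    subs_scale: float = 0.15,
    outgroup_length: float = 0.8,
):
    """Gene family with two planted independent origins.

    Two congruent copies of the species tree (leaf labels ``S|a1`` and
    ``S|b1``) are each paired with a divergent outgroup lineage, so the
    two focal clades are separated by non-focal leaves — the signature of
    independent horizontal origins rather than within-clade duplication.
    Branch lengths are rescaled to substitutions/site. Returns (gene
    tree, taxon map for the gene leaves, the two true member sets); clade
    root supports are set low (50) so delineation must use the AU test or
    the distance criterion rather than bootstrap support.
    """
    from .treeio import TaxonEntry, TaxonMap, parse_newick

    rng = np.random.default_rng(seed)

    def copy_with_suffix(tag: str) -> str:
        # fresh parse: cloning would share (and mutate) the species tree's
        # taxon namespace
        t = dendropy.Tree.get(
            data=species.to_newick() + "\n", schema="newick",
            preserve_underscores=True,
        )
        for leaf in t.leaf_node_iter():
            leaf.taxon.label = f"{leaf.taxon.label}|{tag}1"
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= subs_scale
        t.seed_node.edge.length = None
        newick = t.as_string(schema="newick", suppress_rooting=True).strip()
        return newick.rstrip(";") + f":{outgroup_length * 0.25:.6g}"

    a = copy_with_suffix("a")
    b = copy_with_suffix("b")
    og = outgroup_length
    newick = (
        f"(({a},OG1:{og:g})50:{og * 0.3:g},({b},OG2:{og:g})50:{og * 0.3:g});"
    )
    gt = parse_newick(newick)
    entries = {}
    members_a, members_b = set(), set()
    for lb in gt.leaf_labels():
        if lb.startswith("OG"):
            entries[lb] = TaxonEntry(lb, "outgroup", False)
        else:
            genome = lb.split("|")[0]
            fam = "A" if lb.endswith("a1") else "B"
            (members_a if fam == "A" else members_b).add(lb)
            entries[lb] = TaxonEntry(genome, f"pop_{genome}", True)
    # low support on the focal clade roots themselves
    for node in gt.d.preorder_internal_node_iter():
        leaves = gt.clade_leaves(node)
        if leaves in (frozenset(members_a), frozenset(members_b)):
            node.support = 40.0 + float(rng.integers(0, 20))
    return gt, TaxonMap(entries), (frozenset(members_a), frozenset(members_b))


# ---------------------------------------------------------------------------
# alignments under JC69


def sim_alignment(tree: Tree, n_sites: int, seed: int = 0) -> dict[str, str]:
    """Simulate a nucleotide alignment column-independently under JC69.

    Root states are uniform; substitution probability along a branch of
    length t (substitutions/site) follows the JC69 transition matrix.
    Returns {leaf label: sequence}.
    """
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[id(root)] = rng.integers(0, 4, n_sites)
    seqs: dict[str, str] = {}
    for node in tree.d.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            parent_state = states[id(node.parent_node)]
            change = rng.random(n_sites) < p_change
            shift = rng.integers(1, 4, n_sites)
            state = np.where(change, (parent_state + shift) % 4, parent_state)
            states[id(node)] = state
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(NUCS[states[id(node)]])
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


# ---------------------------------------------------------------------------
# annotated genomes with planted islands


@dataclass
class GenomeLayout:
    """Layout of one simulated genome (single replicon by default)."""

    genome: str = "SIM1"
    replicon: str = "chr1"
    n_genes: int = 2000
    gene_len: int = 900
    spacing: int = 100
    mobile_fraction: float = 0.10
    island_odds_ratio: float = 10.0
    n_islands: int = 3
    lyases_per_island: int = 4
    lyase_gap: int = 4000
    gc_background: float = 0.45
    gc_island: float = 0.35
    gc_window: int = 200


def sim_genome(layout: GenomeLayout, seed: int = 0):
    """Tile genes along a replicon and plant lyase islands.

    Islands carry lyase genes spaced ``lyase_gap`` apart (below the
    region-chaining threshold), an elevated odds of mobile-element
    annotations, and depressed GC. Returns ``(genes, gc_windows, truth)``
    where genes/gc_windows are DataFrames and truth records the island
    spans.
    """
    rng = np.random.default_rng(seed)
    step = layout.gene_len + layout.spacing
    length = layout.n_genes * step + layout.spacing
    p0 = layout.mobile_fraction
    orr = layout.island_odds_ratio
    p1 = orr * p0 / (1 - p0 + orr * p0)

    # choose island blocks: contiguous gene-index windows, non-overlapping
    island_span_genes = max(
        layout.lyases_per_island * (layout.lyase_gap + layout.gene_len) // step + 2, 4
    )
    if layout.n_islands * (island_span_genes + 10) > layout.n_genes:
        raise ValueError("islands overflow the replicon")
    starts: list[int] = []
    slot = layout.n_genes // max(layout.n_islands, 1)
    for i in range(layout.n_islands):
        lo = i * slot
        hi = (i + 1) * slot - island_span_genes - 1
        starts.append(int(rng.integers(lo, max(hi, lo + 1))))
    islands = [(s, s + island_span_genes) for s in starts]

    mobile_cats = ("mobile_element", "integrase", "transposase")
    rows = []
    truth_spans = []
    for gi in range(layout.n_genes):
        start = layout.spacing + gi * step
        end = start + layout.gene_len
        in_island = any(a <= gi < b for a, b in islands)
        p = p1 if in_island else p0
        if rng.random() < p:
            cat = mobile_cats[int(rng.integers(len(mobile_cats)))]
        else:
            cat = "other"
        rows.append(
            dict(
                genome=layout.genome,
                replicon=layout.replicon,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                category=cat,
            )
        )
    # overwrite island lyase positions: evenly spaced lyases inside island
    for a, b in islands:
        span_start = layout.spacing + a * step
        pos = span_start
        members = []
        for k in range(layout.lyases_per_island):
            gi = min(a + (pos - span_start) // step, b - 1)
            rows[gi]["category"] = "lyase_PL7"
            members.append(gi)
            pos += layout.lyase_gap + layout.gene_len
        truth_spans.append(
            dict(
                replicon=layout.replicon,
                start=rows[members[0]]["start"],
                end=rows[members[-1]]["end"],
                n_lyases=len(set(members)),
            )
        )
    genes = pd.DataFrame(rows)

    # GC profile in fixed windows
    win = layout.gc_window
    n_win = length // win + 1
    wstarts = np.arange(n_win) * win
    island_bp = [
        (layout.spacing + a * step, layout.spacing + b * step) for a, b in islands
    ]
    gc_frac = np.full(n_win, layout.gc_background)
    for a_bp, b_bp in island_bp:
        sel = (wstarts >= a_bp) & (wstarts < b_bp)
        gc_frac[sel] = layout.gc_island
    gc_counts = rng.binomial(win, gc_frac)
    gc_windows = pd.DataFrame(
        dict(
            replicon=layout.replicon,
            start=wstarts,
            end=wstarts + win,
            gc_count=gc_counts,
            length=win,
        )
    )
    truth = dict(islands=truth_spans, replicon_length=int(length), p_mobile=(p0, p1))
    return genes, gc_windows, truth


def random_regions(genes: pd.DataFrame, n_regions: int, span: int, seed: int = 0):
    """Regions at category-independent random coordinates.

    Used for null calibration of the enrichment test: because region
    placement is independent of every gene's annotation, the genes falling
    inside the spans are an exchangeable sample and the hypergeometric
    p-value is calibrated. (Lyase-anchored regions are not exchangeable —
    the anchoring genes are categorically non-mobile.)
    """
    from .genome_context import Region

    rng = np.random.default_rng(seed)
    out = []
    for rep, sub in genes.groupby("replicon"):
        length = int(sub["end"].max())
        for _ in range(n_regions):
            start = int(rng.integers(0, max(length - span, 1)))
            out.append(Region(rep, start, start + span, []))
    return out


# ---------------------------------------------------------------------------
# growth curves


def growth_time_grid() -> np.ndarray:
    """Plate-reader sampling grid: hourly to 24 h, 2-hourly to 48 h, 56, 76."""
    return np.concatenate(
        [np.arange(0.0, 24.0, 1.0), np.arange(24.0, 48.0, 2.0), [48.0, 56.0, 76.0]]
    )


def logistic(t: np.ndarray, r: float, K: float, n0: float) -> np.ndarray:
    return K / (1.0 + ((K - n0) / n0) * np.exp(-r * t))


def sim_growth(
    params: pd.DataFrame,
    seed: int = 0,
    replicates: int = 3,
    noise_sigma: float = 0.01,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate delayed-logistic growth curves with lognormal OD noise.

    ``params`` rows need strain, substrate, fraction, r, K, n0, lag;
    a planted non-grower has r == 0 (flat at n0). Returns the long-format
    plate-reader table the pipeline reads.
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = growth_time_grid()
    rows = []
    for rec in params.itertuples():
        for rep in range(1, replicates + 1):
            if rec.r > 0:
                shifted = np.clip(times - rec.lag, 0.0, None)
                od = logistic(shifted, rec.r, rec.K, rec.n0)
            else:
                od = np.full_like(times, rec.n0)
            if noise_sigma > 0:
                od = od * np.exp(rng.normal(0.0, noise_sigma, od.shape))
            for t, y in zip(times, od):
                rows.append(
                    dict(
                        strain=rec.strain,
                        substrate=rec.substrate,
                        fraction=rec.fraction,
                        replicate=rep,
                        time_h=t,
                        od600=y,
                    )
                )
    return pd.DataFrame(rows)
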