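"""Delineation of independently evolving lyase subfamilies.

The procedure mirrors a three-criterion decision chain on a rooted
domain phylogeny whose leaves are labelled focal (the clade of interest)
or outgroup:

1. maximal focal-only clades with strong bootstrap support stand on their
   own;
2. for weakly supported neighbouring clades, the conservative alternative
   ("these clades are one monophyletic subfamily") is compared against the
   ML topology with the approximately unbiased (AU) multiscale-bootstrap
   test on per-site log-likelihoods; failure to reject merges them;
3. inside large mixed clades, subfamilies are recovered by UPGMA
   clustering of patristic distances under a divergence cutoff derived
   from the oldest reference subfamily (maximum root-to-leaf path length,
   0.66 substitutions/site for the reference family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .treeio import TaxonMap, Tree, TreeError, patristic_matrix

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))


@dataclass
class Subfamily:
    id: str
    members: frozenset[str]
    method: str  # bootstrap | au_test | distance_cutoff
    support: float | None = None
    au_p: float | None = None


@dataclass
class SiteLogLikMatrix:
    """Per-site log-likelihoods for >=2 candidate topologies."""

    logliks: np.ndarray  # (n_topologies, n_sites)
    labels: list[str]

    def __post_init__(self):
        self.logliks = np.asarray(self.logliks, dtype=float)
        if self.logliks.ndim != 2 or self.logliks.shape[0] < 2:
            raise ValueError("need a 2D matrix with at least two topologies")
        if self.logliks.shape[1] < 1:
            raise ValueError("need at least one site")
        if not np.isfinite(self.logliks).all():
            raise ValueError("non-finite log-likelihoods")
        if len(self.labels) != self.logliks.shape[0]:
            raise ValueError("label/row mismatch")

    @classmethod
    def from_csv(cls, path) -> "SiteLogLikMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.index))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.logliks,
            index=self.labels,
            columns=[f"site{i+1}" for i in range(self.logliks.shape[1])],
        ).rename_axis("topology").to_csv(path)


@dataclass
class AuResult:
    p_values: dict[str, float]
    bp_scale1: dict[str, float]
    d: dict[str, float]
    c: dict[str, float]
    replicates: int
    seed: int
    degenerate: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# focal clades


def extract_focal_clades(gene_tree: Tree, taxa: TaxonMap) -> list[frozenset[str]]:
    """Maximal clades containing only focal leaves.

    Every returned clade's parent subtree contains at least one outgroup
    leaf (or the clade is the whole tree when no outgroups exist). The
    union of the returned leaf sets is exactly the focal leaf set. A tree
    without focal leaves yields an empty list.
    """
    taxa.validate_tree(gene_tree)
    focal_only: dict[int, bool] = {}
    clades: list[frozenset[str]] = []
    for node in gene_tree.d.postorder_node_iter():
        if node.is_leaf():
            lb = node.taxon.label if node.taxon else node.label
            focal_only[id(node)] = taxa.is_focal(lb)
        else:
            focal_only[id(node)] = all(
                focal_only[id(c)] for c in node.child_nodes()
            )
    for node in gene_tree.d.preorder_node_iter():
        parent = node.parent_node
        if focal_only[id(node)] and (parent is None or not focal_only[id(parent)]):
            clades.append(gene_tree.clade_leaves(node))
    return sorted(clades, key=lambda s: sorted(s))


def clade_support(gene_tree: Tree, members: frozenset[str]) -> float | None:
    """Bootstrap support attached to the clade's root node (if any)."""
    if len(members) == 1:
        return None
    node = gene_tree.mrca(members)
    return getattr(node, "support", None)


def constrain_merge(tree: Tree, clades_to_merge: list[frozenset[str]]) -> Tree:
    """Minimal rearrangement making the union of the clades monophyletic.

    The member clades are pruned, joined into a single pectinate clade
    (preserving each clade's internal topology and stem length), and
    reattached on the edge of the first clade's nearest remaining leaf.
    Branch lengths of the new connecting edges reuse the original stem
    lengths; the result is intended as an alternative hypothesis for
    topology testing (externally re-optimized, or scored as-is by the
    internal likelihood engine as a conservative approximation).
    """
    union = frozenset().union(*clades_to_merge)
    all_leaves = frozenset(tree.leaf_labels())
    if union == all_leaves:
        raise TreeError("cannot merge all leaves: no outgroup context left")
    work = tree.clone()
    if work.mrca(union) is not None and work.clade_leaves(work.mrca(union)) == union:
        return work  # already monophyletic

    dist = patristic_matrix(tree)
    first = clades_to_merge[0]
    remaining = sorted(all_leaves - union)
    # nearest remaining leaf to the first clade (lexicographic tie-break)
    anchor = min(remaining, key=lambda lb: (min(dist.loc[lb, m] for m in first), lb))
    anchor_orig_len = next(
        (l.edge.length for l in tree.leaves()
         if (l.taxon.label if l.taxon else l.label) == anchor),
        None,
    )

    d = work.d
    subtrees = []
    for clade in clades_to_merge:
        node = work.mrca(clade)
        stem = node.edge.length or 0.0
        parent = node.parent_node
        parent.remove_child(node)
        subtrees.append((node, stem))
        _suppress_degree_two(d, parent)
    # rebuild taxon-label lookup after pruning
    merged = subtrees[0][0]
    merged_stem = subtrees[0][1]
    for node, stem in subtrees[1:]:
        joint = type(merged)()
        joint.add_child(merged)
        merged.edge.length = merged_stem
        joint.add_child(node)
        node.edge.length = stem
        merged = joint
        merged_stem = 0.0
    # attach as sister of the anchor leaf, splitting its edge midway
    anchor_node = next(
        l for l in d.leaf_node_iter() if (l.taxon.label if l.taxon else l.label) == anchor
    )
    parent = anchor_node.parent_node
    elen = anchor_node.edge.length
    new = type(anchor_node)()
    parent.remove_child(anchor_node)
    parent.add_child(new)
    if elen is None:
        keep = rest = None
    else:
        # the anchor keeps its original length (pruning may have lengthened
        # its edge); the attachment node takes the accumulated remainder, so
        # the rearrangement perturbs as few path lengths as possible
        keep = anchor_orig_len if anchor_orig_len is not None else elen / 2.0
        keep = min(keep, elen)
        rest = elen - keep
    new.edge.length = rest
    new.add_child(anchor_node)
    anchor_node.edge.length = keep
    new.add_child(merged)
    merged.edge.length = merged_stem
    d.update_taxon_namespace()
    return Tree(d)


def _suppress_degree_two(dtree, node) -> None:
    while node is not None and len(node.child_nodes()) == 1:
        child = node.child_nodes()[0]
        parent = node.parent_node
        el = (node.edge.length or 0.0) + (child.edge.length or 0.0)
        if parent is None:
            # root became degree-1: promote the child
            node.remove_child(child)
            dtree.seed_node = child
            child.parent_node = None
            child.edge.length = None
            return
        parent.remove_child(node)
        parent.add_child(child)
        child.edge.length = el
        node = parent


# ---------------------------------------------------------------------------
# JC69 per-site log-likelihoods (Felsenstein pruning)


def site_loglik(alignment: dict[str, str], tree: Tree) -> np.ndarray:
    """Per-site log-likelihood vector under JC69 with uniform root prior.

    Gaps and ambiguity codes are treated as missing (partial likelihood 1
    over all four states). Alignment rows must match the tree's leaves.
    """
    leaves = set(tree.leaf_labels())
    if leaves != set(alignment):
        raise ValueError(
            f"alignment rows {sorted(set(alignment))} do not match tree leaves "
            f"{sorted(leaves)}"
        )
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    n_sites = lengths.pop()
    idx = {b: i for i, b in enumerate("ACGT")}

    def pmatrix(t: float) -> np.ndarray:
        e = np.exp(-4.0 * t / 3.0)
        same = 0.25 + 0.75 * e
        diff = 0.25 - 0.25 * e
        p = np.full((4, 4), diff)
        np.fill_diagonal(p, same)
        return p

    partials: dict[int, np.ndarray] = {}
    for node in tree.d.postorder_node_iter():
        if node.is_leaf():
            seq = alignment[node.taxon.label if node.taxon else node.label].upper()
            part = np.zeros((4, n_sites))
            for s, base in enumerate(seq):
                if base in idx:
                    part[idx[base], s] = 1.0
                else:
                    part[:, s] = 1.0
            partials[id(node)] = part
        else:
            part = np.ones((4, n_sites))
            for child in node.child_nodes():
                p = pmatrix(child.edge.length or 0.0)
                part *= p @ partials[id(child)]
            partials[id(node)] = part
    site_lik = 0.25 * partials[id(tree.root)].sum(axis=0)
    return np.log(site_lik)


# ---------------------------------------------------------------------------
# AU test (multiscale RELL bootstrap, Shimodaira's signed-distance fit)


def au_test(
    matrix: SiteLogLikMatrix,
    scales=DEFAULT_SCALES,
    replicates: int = 10000,
    seed: int = 0,
) -> AuResult:
    """Approximately unbiased topology test.

    At each scale r, ceil(r * n_sites) site columns are RELL-resampled
    with replacement and the winning-topology frequency recorded (exact
    ties share the replicate equally). The bootstrap proportions are fit
    by weighted least squares to 1 - Phi(d*sqrt(r) + c/sqrt(r)); the AU
    p-value is 1 - Phi(d - c). A topology that wins (or ties for the win)
    in every replicate at every scale is degenerate with p = 1; one that
    never wins is degenerate with p = 0.
    """
    L = matrix.logliks
    n_topo, n_sites = L.shape
    rng = np.random.default_rng(seed)
    scales = list(scales)
    bp = np.zeros((len(scales), n_topo))
    always_max = np.ones(n_topo, dtype=bool)
    never_max = np.ones(n_topo, dtype=bool)
    for si, r in enumerate(scales):
        m = int(np.ceil(r * n_sites))
        counts = np.zeros(n_topo)
        for _ in range(replicates):
            draw = rng.integers(0, n_sites, m)
            weights = np.bincount(draw, minlength=n_sites)
            sums = L @ weights
            mx = sums.max()
            winners = np.isclose(sums, mx, rtol=0.0, atol=1e-9)
            counts += winners / winners.sum()
            always_max &= winners
            never_max &= ~winners
        bp[si] = counts / replicates

    p_values, d_out, c_out, degenerate = {}, {}, {}, {}
    sq = np.sqrt(np.asarray(scales))
    for t in range(n_topo):
        label = matrix.labels[t]
        if always_max[t]:
            p_values[label], degenerate[label] = 1.0, True
            d_out[label] = c_out[label] = float("nan")
            continue
        if never_max[t]:
            p_values[label], degenerate[label] = 0.0, True
            d_out[label] = c_out[label] = float("nan")
            continue
        props = bp[:, t]
        usable = (props > 0.0) & (props < 1.0)
        if usable.sum() < 2:
            # proportions pinned at 0/1 at nearly all scales
            p = 1.0 if props.mean() > 0.5 else 0.0
            p_values[label], degenerate[label] = p, True
            d_out[label] = c_out[label] = float("nan")
            continue
        z = norm.isf(props[usable])  # Phi^-1(1 - bp)
        w = replicates * norm.pdf(z) ** 2 / (props[usable] * (1 - props[usable]))
        X = np.column_stack([sq[usable], 1.0 / sq[usable]])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
        d, c = beta
        p_values[label] = float(norm.sf(d - c))
        d_out[label], c_out[label] = float(d), float(c)
        degenerate[label] = False
    scale1 = min(range(len(scales)), key=lambda i: abs(scales[i] - 1.0))
    return AuResult(
        p_values=p_values,
        bp_scale1={matrix.labels[t]: float(bp[scale1, t]) for t in range(n_topo)},
        d=d_out,
        c=c_out,
        replicates=replicates,
        seed=seed,
        degenerate=degenerate,
    )


def naive_rell_bootstrap(
    matrix: SiteLogLikMatrix, replicates: int = 10000, seed: int = 0
) -> dict[str, float]:
    """Plain scale-1 RELL bootstrap proportions (reference implementation)."""
    L = matrix.logliks
    n_topo, n_sites = L.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_topo)
    for _ in range(replicates):
        cols = rng.integers(0, n_sites, n_sites)
        sums = L[:, cols].sum(axis=1)
        winners = np.isclose(sums, sums.max(), rtol=0.0, atol=1e-9)
        counts += winners / winners.sum()
    return {matrix.labels[t]: counts[t] / replicates for t in range(n_topo)}


# ---------------------------------------------------------------------------
# distance-based criterion


def derive_cutoff(reference_subfamily_tree: Tree) -> float:
    """Maximum root-to-leaf path length of a reference subfamily.

    The oldest well-supported subfamily bounds the divergence expected
    within any single subfamily; its deepest leaf sets the clustering
    cutoff (0.66 substitutions/site for the published reference family).
    """
    tree = reference_subfamily_tree
    if tree.root.is_leaf():
        # degenerate single-leaf subtree: its depth is the stem length
        if tree.root.edge.length is None:
            raise TreeError("reference subtree lacks branch lengths")
        return float(tree.root.edge.length)
    for edge in tree.d.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise TreeError("reference subtree lacks branch lengths")
    depths = tree.depths()
    return max(depths[l] for l in tree.leaves())


def cluster_by_cutoff(distances: pd.DataFrame, cutoff: float) -> list[frozenset[str]]:
    """UPGMA (average linkage) clusters cut at the given height.

    Merging proceeds while the smallest average-linkage distance does not
    exceed the cutoff; equal-distance candidates are resolved by merging
    the pair with the lexicographically smallest member labels. Raising
    the cutoff never splits an existing cluster.
    """
    if not np.allclose(distances.values, distances.values.T):
        raise ValueError("distance matrix must be symmetric")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    labels = list(distances.index)
    clusters: dict[tuple[str, ...], list[str]] = {
        (lb,): [lb] for lb in labels
    }
    dist = {
        frozenset(((a,), (b,))): float(distances.loc[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }
    keys = {(lb,): lb for lb in labels}  # cluster -> sort key (min label)
    while len(clusters) > 1:
        best = None
        for ka in clusters:
            for kb in clusters:
                if keys[ka] >= keys[kb]:
                    continue
                d = dist[frozenset((ka, kb))]
                cand = (d, keys[ka], keys[kb], ka, kb)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        d, _, _, ka, kb = best
        if d > cutoff:
            break
        na, nb = len(clusters[ka]), len(clusters[kb])
        merged = tuple(sorted(clusters[ka] + clusters[kb]))
        for kc in list(clusters):
            if kc in (ka, kb):
                continue
            dc = (
                na * dist[frozenset((ka, kc))] + nb * dist[frozenset((kb, kc))]
            ) / (na + nb)
            dist[frozenset((merged, kc))] = dc
        clusters[merged] = clusters.pop(ka) + clusters.pop(kb)
        keys[merged] = min(keys.pop(ka), keys.pop(kb))
    return sorted(
        (frozenset(v) for v in clusters.values()), key=lambda s: sorted(s)
    )


# ---------------------------------------------------------------------------
# full delineation


def delineate(
    gene_tree: Tree,
    taxa: TaxonMap,
    bootstrap_threshold: float = 70.0,
    merge_candidates: list[list[int]] | None = None,
    loglik_matrices: list[SiteLogLikMatrix] | None = None,
    alignment: dict[str, str] | None = None,
    cutoff: float | None = None,
    alpha: float = 0.05,
    replicates: int = 10000,
    seed: int = 0,
) -> list[Subfamily]:
    """Three-criterion subfamily delineation.

    Initial clades come from :func:`extract_focal_clades`. Clades whose
    bootstrap support meets ``bootstrap_threshold`` stand. For the
    explicitly named low-support ``merge_candidates`` (groups of initial
    clade indices), the merged alternative topology is AU-tested against
    the supplied tree: per-site log-likelihoods are taken from
    ``loglik_matrices`` (one per group, topology labels 'ml' and 'merged')
    or computed from ``alignment`` under JC69 with the supplied branch
    lengths. A non-rejected alternative (p >= alpha) merges the group;
    rejection keeps the clades separate. Any remaining low-support clades
    are re-partitioned by UPGMA under ``cutoff``. Low-support clades with
    no resolution path raise an error.
    """
    initial = extract_focal_clades(gene_tree, taxa)
    if not initial:
        return []
    supports = [clade_support(gene_tree, c) for c in initial]
    out: list[Subfamily] = []
    resolved: set[int] = set()
    for i, (clade, sup) in enumerate(zip(initial, supports)):
        if sup is not None and sup >= bootstrap_threshold:
            out.append(Subfamily(f"SF{i+1}", clade, "bootstrap", support=sup))
            resolved.add(i)

    merge_candidates = merge_candidates or []
    for gi, group in enumerate(merge_candidates):
        bad = [i for i in group if not 0 <= i < len(initial)]
        if bad:
            raise ValueError(
                f"merge candidate indices {bad} out of range: only "
                f"{len(initial)} initial clades"
            )
        group = [i for i in group if i not in resolved]
        if len(group) < 2:
            continue
        clades = [initial[i] for i in group]
        if loglik_matrices is not None:
            matrix = loglik_matrices[gi]
        elif alignment is not None:
            alt = constrain_merge(gene_tree, clades)
            matrix = SiteLogLikMatrix(
                np.vstack(
                    [site_loglik(alignment, gene_tree), site_loglik(alignment, alt)]
                ),
                ["ml", "merged"],
            )
        else:
            raise ValueError(
                "merge candidates supplied but neither loglik_matrices nor "
                "alignment given"
            )
        res = au_test(matrix, replicates=replicates, seed=seed + gi)
        p_alt = res.p_values["merged"]
        if p_alt >= alpha:
            members = frozenset().union(*clades)
            out.append(
                Subfamily(f"SF{group[0]+1}", members, "au_test", au_p=p_alt)
            )
        else:
            for i in group:
                out.append(
                    Subfamily(
                        f"SF{i+1}", initial[i], "au_test",
                        support=supports[i], au_p=p_alt,
                    )
                )
        resolved.update(group)

    unresolved = [i for i in range(len(initial)) if i not in resolved]
    if unresolved:
        if cutoff is None:
            raise ValueError(
                "low-support clades remain but no AU matrix and no distance "
                f"cutoff supplied (clade indices {unresolved})"
            )
        leaves = sorted(frozenset().union(*(initial[i] for i in unresolved)))
        dm = patristic_matrix(gene_tree).loc[leaves, leaves]
        for k, cluster in enumerate(cluster_by_cutoff(dm, cutoff)):
            out.append(Subfamily(f"SFd{k+1}", cluster, "distance_cutoff"))

    _check_partition(out, initial)
    return out


def _check_partition(subfamilies: list[Subfamily], initial) -> None:
    seen: set[str] = set()
    for sf in subfamilies:
        overlap = seen & set(sf.members)
        if overlap:
            raise AssertionError(f"leaf assigned twice: {sorted(overlap)}")
        seen |= set(sf.members)
    expected = set().union(*initial) if initial else set()
    if seen != expected:
        raise AssertionError("delineation lost or invented focal leaves")


def subfamilies_to_frame(subfamilies: list[Subfamily]) -> pd.DataFrame:
    rows = []
    for sf in subfamilies:
        for leaf in sorted(sf.members):
            rows.append(
                dict(
                    leaf=leaf,
                    subfamily=sf.id,
                    method=sf.method,
                    support=sf.support,
                    au_p=sf.au_p,
                )
            )
    return pd.DataFrame(rows, columns=["leaf", "subfamily", "method", "support", "au_p"])
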