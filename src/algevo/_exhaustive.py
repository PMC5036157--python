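"""Naive exhaustive DTL scoring for tiny instances.

A memoisation-free recursion over the same event grammar as the DP in
:mod:`algevo.reconcile` (speciation, duplication, transfer to a
contemporaneous branch, speciation-with-loss, pass-through), written
directly from the event semantics with no alive-set precomputation or
candidate pruning. Exponential in instance size; intended as a reference
check for gene trees and species trees with at most ~4 leaves each.
"""

from __future__ import annotations

import math

from .treeio import DatedTree, Tree

INF = math.inf


def _alive(species: DatedTree, bid, lo: float, hi: float) -> list[str]:
    out = []
    for n in species.d.preorder_node_iter():
        if n.parent_node is None:
            continue
        if species.times[n.parent_node] <= lo + 1e-12 and species.times[n] >= hi - 1e-12:
            out.append(bid[n])
    return out


def exhaustive_min_cost(
    gene_tree: Tree,
    species: DatedTree,
    leaf_map: dict[str, str],
    loss: float = 1.0,
    duplication: float = 2.0,
    transfer: float = 3.0,
    slices_per_interval: int = 1,
    forced_birth: tuple[str, int] | None = None,
) -> float:
    """Minimum event cost by brute-force recursion over all histories."""
    from .synthetic_data import branch_ids

    bid = branch_ids(species)
    node_of = {v: k for k, v in bid.items()}
    times = sorted({species.times[n] for n in species.d.preorder_node_iter()})
    bounds = [(0.0, 0.0)]
    for lo, hi in zip(times, times[1:]):
        step = (hi - lo) / slices_per_interval
        bounds.extend(
            (lo + step * k, lo + step * (k + 1)) for k in range(slices_per_interval)
        )
    alive = [
        [bid[species.root]] if i == 0 else _alive(species, bid, lo, hi)
        for i, (lo, hi) in enumerate(bounds)
    ]
    last = len(bounds) - 1

    def cost(gnode, branch: str, si: int) -> float:
        options = [descend(gnode, branch, si)]
        kids = gnode.child_nodes()
        if kids:
            u1, u2 = kids
            options.append(duplication + cost(u1, branch, si) + cost(u2, branch, si))
            for other in alive[si]:
                if other == branch:
                    continue
                options.append(transfer + cost(u1, branch, si) + cost(u2, other, si))
                options.append(transfer + cost(u2, branch, si) + cost(u1, other, si))
        return min(options)

    def descend(gnode, branch: str, si: int) -> float:
        if si == last:
            label = gnode.taxon.label if gnode.taxon else gnode.label
            if not gnode.child_nodes() and leaf_map[label] == branch:
                return 0.0
            return INF
        node = node_of[branch]
        if species.times[node] > bounds[si][1] + 1e-12:
            return cost_at_next(gnode, branch, si + 1)
        kids = node.child_nodes()
        if not kids:
            return INF
        b1, b2 = bid[kids[0]], bid[kids[1]]
        options = [
            loss + cost_at_next(gnode, b1, si + 1),
            loss + cost_at_next(gnode, b2, si + 1),
        ]
        gkids = gnode.child_nodes()
        if gkids:
            u1, u2 = gkids
            options.append(cost_at_next(u1, b1, si + 1) + cost_at_next(u2, b2, si + 1))
            options.append(cost_at_next(u1, b2, si + 1) + cost_at_next(u2, b1, si + 1))
        return min(options)

    def cost_at_next(gnode, branch: str, si: int) -> float:
        if branch not in alive[si]:
            return INF
        return cost(gnode, branch, si)

    root = gene_tree.root
    if forced_birth is not None:
        b, si = forced_birth
        if b not in alive[si]:
            return INF
        return cost(root, b, si)
    best = INF
    for si in range(len(bounds)):
        for b in alive[si]:
            best = min(best, cost(root, b, si))
    return best


def exhaustive_cooptimal_births(
    gene_tree: Tree,
    species: DatedTree,
    leaf_map: dict[str, str],
    slices_per_interval: int = 1,
    **cost_kwargs,
) -> set[tuple[str, int]]:
    """All birth placements achieving the brute-force minimum."""
    from .synthetic_data import branch_ids

    bid = branch_ids(species)
    times = sorted({species.times[n] for n in species.d.preorder_node_iter()})
    n_slices = 1 + (len(times) - 1) * slices_per_interval
    best = exhaustive_min_cost(
        gene_tree, species, leaf_map,
        slices_per_interval=slices_per_interval, **cost_kwargs,
    )
    out = set()
    for si in range(n_slices):
        for b in bid.values():
            c = exhaustive_min_cost(
                gene_tree, species, leaf_map,
                slices_per_interval=slices_per_interval,
                forced_birth=(b, si), **cost_kwargs,
            )
            if math.isclose(c, best, abs_tol=1e-9):
                out.add((b, si))
    return out
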