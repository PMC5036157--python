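"""Phylogeny parsing, validation and distance services.

Trees are thin wrappers around :mod:`dendropy` trees that enforce the
invariants every downstream stage relies on: a single root, unique leaf
labels, non-negative branch lengths, and (for dated trees) node times that
increase from the root (time 0) to contemporaneous tips.

Support values follow the RAxML convention of internal-node labels; a flag
selects the branch-label (bracket comment) dialect instead.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


class TreeError(ValueError):
    """Malformed or invariant-violating tree input."""


class Tree:
    """Rooted phylogeny with optional branch lengths and supports.

    Parameters
    ----------
    dtree:
        A rooted :class:`dendropy.Tree`. The wrapper validates invariants
        on construction and exposes convenience accessors; the underlying
        dendropy object remains available as ``.d``.
    """

    def __init__(self, dtree: dendropy.Tree):
        self.d = dtree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, support_dialect: str = "internal_label") -> "Tree":
        return parse_newick(text, support_dialect=support_dialect)

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.d.leaf_node_iter():
            label = _leaf_label(leaf)
            if label is None:
                raise TreeError("leaf without a taxon label")
            if label in seen:
                raise TreeError(f"duplicate leaf label: {label!r}")
            seen.add(label)
        if not seen:
            raise TreeError("tree has no leaves")
        for edge in self.d.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")

    # -- accessors --------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.d.seed_node

    def leaves(self) -> list[dendropy.Node]:
        return list(self.d.leaf_node_iter())

    def leaf_labels(self) -> list[str]:
        return [_leaf_label(n) for n in self.leaves()]

    def nodes(self):
        return self.d.preorder_node_iter()

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) in (0, 2) for n in self.d.preorder_node_iter()
        )

    def support(self, node: dendropy.Node) -> float | None:
        return getattr(node, "support", None)

    def height(self) -> float:
        return max(self.depths().values())

    def depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path lengths (missing lengths count as 0)."""
        out: dict[dendropy.Node, float] = {}
        for node in self.d.preorder_node_iter():
            parent = node.parent_node
            el = node.edge.length or 0.0
            out[node] = (out[parent] if parent is not None else 0.0) + (
                el if parent is not None else 0.0
            )
        return out

    def mrca(self, labels) -> dendropy.Node:
        labels = list(labels)
        leaves = {_leaf_label(n): n for n in self.leaves()}
        missing = [lb for lb in labels if lb not in leaves]
        if missing:
            raise TreeError(f"no leaf labelled {missing[0]!r}")
        chain = []
        node = leaves[labels[0]]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        index_of = {id(n): i for i, n in enumerate(chain)}
        deepest = 0
        for lb in labels[1:]:
            node = leaves[lb]
            while id(node) not in index_of:
                node = node.parent_node
            deepest = max(deepest, index_of[id(node)])
        return chain[deepest]

    def _taxon_for(self, label: str):
        for leaf in self.leaves():
            if _leaf_label(leaf) == label:
                return leaf.taxon
        raise TreeError(f"no leaf labelled {label!r}")

    def clade_leaves(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(_leaf_label(l) for l in node.leaf_iter())

    # -- output -----------------------------------------------------------

    def to_newick(self, support_dialect: str = "internal_label") -> str:
        return write_newick(self, support_dialect=support_dialect)

    def clone(self) -> "Tree":
        return Tree(self.d.clone(depth=1))

    def reroot_on_outgroup(self, outgroup_labels) -> "Tree":
        """Convenience rerooting on the stem edge of a named leaf set."""
        t = self.d.clone(depth=1)
        mrca = t.mrca(taxon_labels=list(outgroup_labels))
        if mrca is t.seed_node:
            raise TreeError("outgroup spans the current root; cannot reroot")
        t.reroot_at_edge(mrca.edge, update_bipartitions=False)
        return Tree(t)


class DatedTree(Tree):
    """Ultrametric tree with node times (root 0, tips equal and maximal)."""

    def __init__(self, dtree: dendropy.Tree, tolerance: float = 1e-6):
        super().__init__(dtree)
        depths = self.depths()
        height = max(depths.values())
        if height <= 0:
            raise TreeError("dated tree must have positive root-to-tip span")
        tol_abs = tolerance * height
        leaves = self.leaves()
        shallow = min(leaves, key=lambda l: depths[l])
        deep = max(leaves, key=lambda l: depths[l])
        if depths[deep] - depths[shallow] > tol_abs:
            raise TreeError(
                "tree is not ultrametric within tolerance: leaf depths "
                f"{depths[shallow]:.6g} ({_leaf_label(shallow)}) vs "
                f"{depths[deep]:.6g} ({_leaf_label(deep)})"
            )
        # snap leaf times to the common tip time so rounding noise in the
        # input lengths cannot make a leaf end "before the present"
        for leaf in leaves:
            depths[leaf] = height
        self.times: dict[dendropy.Node, float] = depths
        self.tip_time: float = height
        for node, t in depths.items():
            node.time = t

    def clone(self) -> "DatedTree":
        return DatedTree(self.d.clone(depth=1))


@dataclass(frozen=True)
class TaxonEntry:
    genome: str
    population: str
    focal: bool = True


@dataclass
class TaxonMap:
    """Leaf label -> (genome, population, focal flag)."""

    entries: dict[str, TaxonEntry] = field(default_factory=dict)

    def __getitem__(self, leaf: str) -> TaxonEntry:
        try:
            return self.entries[leaf]
        except KeyError:
            raise KeyError(f"leaf {leaf!r} not in taxon map") from None

    def __contains__(self, leaf: str) -> bool:
        return leaf in self.entries

    def is_focal(self, leaf: str) -> bool:
        return self[leaf].focal

    def population(self, leaf: str) -> str:
        return self[leaf].population

    def genome(self, leaf: str) -> str:
        return self[leaf].genome

    def populations(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for leaf, e in self.entries.items():
            out.setdefault(e.population, []).append(leaf)
        return out

    def validate_tree(self, tree: Tree) -> None:
        missing = [lb for lb in tree.leaf_labels() if lb not in self.entries]
        if missing:
            raise KeyError(f"gene-tree leaves absent from taxon map: {missing}")

    @classmethod
    def from_csv(cls, path_or_buf) -> "TaxonMap":
        df = pd.read_csv(path_or_buf)
        required = {"leaf", "genome", "population"}
        if not required.issubset(df.columns):
            raise ValueError(f"taxon map CSV needs columns {sorted(required)}")
        focal = (
            df["focal"].astype(bool)
            if "focal" in df.columns
            else pd.Series(True, index=df.index)
        )
        entries = {
            str(r.leaf): TaxonEntry(str(r.genome), str(r.population), bool(f))
            for r, f in zip(df.itertuples(), focal)
        }
        if not entries:
            raise ValueError("empty taxon map")
        return cls(entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["leaf", "genome", "population", "focal"])
            for leaf in sorted(self.entries):
                e = self.entries[leaf]
                w.writerow([leaf, e.genome, e.population, int(e.focal)])


# ---------------------------------------------------------------------------
# newick I/O


def _leaf_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label


def parse_newick(text: str, support_dialect: str = "internal_label") -> Tree:
    """Parse one rooted tree from a Newick string.

    ``support_dialect='internal_label'`` (RAxML style) interprets internal
    node labels as bootstrap supports; ``'branch_label'`` reads supports
    from square-bracket comments attached to the branch instead.
    """
    if support_dialect not in ("internal_label", "branch_label", "none"):
        raise ValueError(f"unknown support dialect {support_dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "column", None)
        loc = f" near character {offset}" if offset is not None else ""
        raise TreeError(f"malformed Newick{loc}: {exc}") from exc
    dtree.suppress_unifurcations()
    for node in dtree.preorder_internal_node_iter():
        support = None
        if support_dialect == "internal_label" and node.label not in (None, ""):
            try:
                support = float(node.label)
            except ValueError:
                support = None
        elif support_dialect == "branch_label":
            comments = list(getattr(node.edge, "comments", []) or []) + list(
                getattr(node, "comments", []) or []
            )
            for c in comments:
                try:
                    support = float(c)
                    break
                except ValueError:
                    continue
        if support is not None:
            node.support = support
    return Tree(dtree)


def write_newick(tree: Tree, support_dialect: str = "internal_label") -> str:
    """Serialise with 10-significant-digit branch lengths."""
    t = tree.d
    for node in t.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and support_dialect == "internal_label":
            node.label = f"{sup:g}"
    out = t.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()
    return out


def read_newick_file(path, support_dialect: str = "internal_label") -> list[Tree]:
    with open(path) as fh:
        text = fh.read()
    trees = []
    for chunk in text.replace("\n", " ").split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";", support_dialect=support_dialect))
    return trees


# ---------------------------------------------------------------------------
# operations


def as_dated(tree: Tree, tolerance: float = 1e-6) -> DatedTree:
    """Interpret an ultrametric tree as a relative-timed (dated) tree.

    Node time equals the root-to-node path length; leaves must be
    contemporaneous within ``tolerance`` (a fraction of tree height).
    Idempotent on trees that are already dated.
    """
    if isinstance(tree, DatedTree):
        return tree
    return DatedTree(tree.d, tolerance=tolerance)


def patristic_matrix(tree: Tree) -> pd.DataFrame:
    """Leaf x leaf matrix of path-length (patristic) distances."""
    for edge in tree.d.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise TreeError("patristic distances require branch lengths on all edges")
    labels = sorted(tree.leaf_labels())
    depths = tree.depths()
    leaves = {_leaf_label(n): n for n in tree.leaves()}
    # d(i,j) = depth_i + depth_j - 2*depth(mrca)
    ancestors: dict[str, list] = {}
    for lb, leaf in leaves.items():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        ancestors[lb] = chain
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        seta = set(id(x) for x in ancestors[a])
        for j in range(i + 1, n):
            b = labels[j]
            mrca = next(x for x in ancestors[b] if id(x) in seta)
            d = depths[leaves[a]] + depths[leaves[b]] - 2 * depths[mrca]
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)
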