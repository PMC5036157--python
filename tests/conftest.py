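import random

import pytest

from algevo import synthetic_data as sd
from algevo import treeio
from algevo.treeio import TaxonEntry, TaxonMap


@pytest.fixture
def three_taxon_dated():
    """((A:1,B:1):1,C:2); — the smallest non-trivial dated tree."""
    return treeio.as_dated(treeio.parse_newick("((A:1,B:1):1,C:2);"))


@pytest.fixture
def focal_map():
    """F* leaves focal, O* leaves outgroup."""

    def make(labels):
        return TaxonMap(
            {
                lb: TaxonEntry(lb, "pop", not lb.startswith("O"))
                for lb in labels
            }
        )

    return make


@pytest.fixture
def random_gene_tree():
    """Random rooted binary gene tree over species leaves (with repeats)."""

    def make(rng: random.Random, species_leaves, n_leaves):
        labels = [
            f"{rng.choice(list(species_leaves))}|g{i}" for i in range(n_leaves)
        ]
        nodes = [f"{lb}:1" for lb in labels]
        while len(nodes) > 1:
            a = nodes.pop(rng.randrange(len(nodes)))
            b = nodes.pop(rng.randrange(len(nodes)))
            nodes.append(f"({a},{b}):1")
        tree = treeio.parse_newick(nodes[0] + ";")
        return tree, {lb: lb.split("|")[0] for lb in labels}

    return make


@pytest.fixture
def species_tree_factory():
    def make(n, seed):
        return sd.sim_species_tree(n, seed=seed)

    return make
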