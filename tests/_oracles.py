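"""Independent oracles shared by the test modules."""


def pruned_lineage_count(sp, final_counts) -> int:
    """Parsimony loss count for a loss-only family: the number of maximal
    species clades without a surviving copy *inside* the subtree rooted at
    the MRCA of the surviving species (the free birth is placed there, so
    absences outside that subtree are never charged)."""
    survivors = [s for s, n in final_counts.items() if n > 0]
    mrca = sp.mrca(survivors)
    survives = {}
    for node in mrca.postorder_iter():
        if node.is_leaf():
            survives[id(node)] = final_counts.get(node.taxon.label, 0) > 0
        else:
            survives[id(node)] = any(
                survives[id(c)] for c in node.child_nodes()
            )
    count = 0
    for node in mrca.preorder_iter():
        parent = node.parent_node
        if not survives[id(node)] and (node is mrca or survives[id(parent)]):
            count += 1
    return count
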