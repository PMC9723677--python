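"""Small tree helpers shared by the RED and trait-history modules."""

from __future__ import annotations

import dendropy

__all__ = ["mrca"]


def mrca(tree: dendropy.Tree, leaf_labels: set[str]) -> dendropy.Node | None:
    """Most recent common ancestor of the named leaves, relative to the
    current root.

    Unlike :meth:`dendropy.Tree.mrca` this never re-encodes bipartitions,
    so it cannot mutate the tree (dendropy collapses basal bifurcations of
    unrooted trees when encoding). Returns None if no named leaf is in the
    tree.
    """
    wanted = set(leaf_labels)
    if not wanted:
        return None
    counts: dict[dendropy.Node, int] = {}
    total = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            hit = 1 if node.taxon is not None and node.taxon.label in wanted else 0
            counts[node] = hit
            total += hit
        else:
            counts[node] = sum(counts[c] for c in node.child_nodes())
    if total == 0:
        return None
    for node in tree.postorder_node_iter():
        if counts[node] == total:
            return node
    return tree.seed_node
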