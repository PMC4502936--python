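"""Family-level phylogeny input and patristic distances.

The phylogenetic-signal test needs only a labelled distance matrix: the
patristic distance between two tips is the sum of branch lengths along the
path connecting them.  Trees are read from Newick (dendropy does the
parsing); the tree itself is user-supplied — typically a published
family-level phylogeny pruned to the sampled families — or a simulated
stand-in from :mod:`wolbprev.synthetic`.
"""

from __future__ import annotations

import dendropy

from .geospatial import DistanceMatrix

__all__ = ["read_newick", "patristic_matrix"]


def _validate(tree: dendropy.Tree) -> None:
    names = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(n is None for n in names):
        raise ValueError("tree has unnamed tips")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate tip names: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"branch leading to {edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'} "
                "has no length; patristic distances need branch lengths"
            )
        if edge.length < 0:
            raise ValueError("negative branch length")


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree with branch lengths; validates unique named tips."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ValueError(f"failed to parse newick file {path}: {exc}") from exc
    _validate(tree)
    return tree


def patristic_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> DistanceMatrix:
    """Patristic (path-length) distance matrix over the requested tips.

    ``taxa`` defaults to all tips in tree order; an absent taxon raises a
    lookup error naming it.
    """
    _validate(tree)
    pdm = tree.phylogenetic_distance_matrix()
    tip = {t.label: t for t in tree.taxon_namespace if tree.taxon_namespace}
    # restrict to actual leaves
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if taxa is None:
        taxa = leaf_labels
    missing = [t for t in taxa if t not in leaf_labels]
    if missing:
        raise KeyError(f"taxa not found as tree tips: {missing}")
    import numpy as np

    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tip[taxa[i]], tip[taxa[j]])
    return DistanceMatrix(list(taxa), d)
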