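"""Distance-based tree construction (NJ, UPGMA), bootstrap support, and
Robinson-Foulds comparison.

Trees are :class:`dendropy.Tree` objects.  Neighbor joining follows the
classic Saitou-Nei/Studier-Keppler formulation with two determinism rules:
ties in the Q criterion are broken by the lowest (row, column) index pair, and
a negative branch length is clamped to zero with the deficit moved onto the
sibling branch so the pair's path length is preserved.
"""

from __future__ import annotations

import random
from typing import Callable, Sequence

import dendropy
import numpy as np

__all__ = [
    "nj_tree",
    "upgma_tree",
    "bootstrap_support",
    "rf_distance",
    "bipartitions",
]


def _check_matrix(d: np.ndarray, taxa: Sequence[str]) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] != len(taxa):
        raise ValueError("matrix size does not match number of taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxon labels must be unique")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def _new_tree(taxa: Sequence[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = {}
    for t in taxa:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=t)
        nodes[t] = node
    return tree, nodes


def nj_tree(d, taxa: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Requires at least 3 taxa.  The returned tree is unrooted (stored with a
    basal trifurcation where possible).
    """
    d = _check_matrix(d, taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    tree, leaf_nodes = _new_tree(taxa)
    active: list[dendropy.Node] = [leaf_nodes[t] for t in taxa]
    dist = {(a, b): d[i, j] for i, a in enumerate(active) for j, b in enumerate(active) if i < j}

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b is not a) for a in active}
        best = None
        best_q = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        a, b = active[i], active[j]
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sibling branch
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        u = dendropy.Node()
        u.add_child(a)
        u.add_child(b)
        a.edge.length = la
        b.edge.length = lb
        for c in active:
            if c is a or c is b:
                continue
            dist[(u, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = [c for c in active if c is not a and c is not b]
        active.append(u)

    # final trifurcation from the three-point formulas
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    root = dendropy.Node()
    for node, ln in ((a, 0.5 * (dab + dac - dbc)),
                     (b, 0.5 * (dab + dbc - dac)),
                     (c, 0.5 * (dac + dbc - dab))):
        root.add_child(node)
        node.edge.length = max(0.0, ln)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def upgma_tree(d, taxa: Sequence[str]) -> dendropy.Tree:
    """UPGMA (average-linkage) ultrametric tree.  Ties are broken by the
    lowest (row, column) index pair in current cluster-creation order."""
    d = _check_matrix(d, taxa)
    n = len(taxa)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    tree, leaf_nodes = _new_tree(taxa)
    active = [leaf_nodes[t] for t in taxa]
    size = {a: 1 for a in active}
    height = {a: 0.0 for a in active}
    dist = {(a, b): d[i, j] for i, a in enumerate(active) for j, b in enumerate(active) if i < j}

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    while len(active) > 1:
        m = len(active)
        best, best_d = None, None
        for i in range(m):
            for j in range(i + 1, m):
                dd = get(active[i], active[j])
                if best_d is None or dd < best_d - 1e-12:
                    best_d, best = dd, (i, j)
        i, j = best
        a, b = active[i], active[j]
        u = dendropy.Node()
        h = best_d / 2.0
        u.add_child(a)
        u.add_child(b)
        a.edge.length = h - height[a]
        b.edge.length = h - height[b]
        height[u] = h
        size[u] = size[a] + size[b]
        for c in active:
            if c is a or c is b:
                continue
            dist[(u, c)] = (size[a] * get(a, c) + size[b] * get(b, c)) / (size[a] + size[b])
        active = [c for c in active if c is not a and c is not b]
        active.append(u)

    tree.seed_node = active[0]
    tree.is_rooted = True
    tree.update_taxon_namespace()
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree, each encoded as the
    frozenset of leaf labels on the side not containing the first leaf."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_set) - 1:
            continue
        if ref in side:
            side = all_set - side
        out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds bipartition distance (symmetric difference count)."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(matrix_builder: Callable[[np.ndarray], tuple[np.ndarray, Sequence[str]]],
                      n_columns: int,
                      tree_builder: Callable = nj_tree,
                      reps: int = 1000,
                      seed: int = 0) -> dendropy.Tree:
    """Bootstrap support for a column-resampled distance analysis.

    ``matrix_builder(column_index_array) -> (distance_matrix, taxa)`` computes
    the distance matrix from a multiset of alignment columns; the full tree is
    built from the identity resample and each replicate from ``n_columns``
    columns drawn with replacement.  Support (percentage of replicates
    containing each internal bipartition) is written to ``node.label`` of the
    full tree's internal nodes.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = random.Random(seed)
    base_cols = np.arange(n_columns)
    d, taxa = matrix_builder(base_cols)
    tree = tree_builder(d, taxa)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    for _ in range(reps):
        cols = np.array([rng.randrange(n_columns) for _ in range(n_columns)])
        rd, rtaxa = matrix_builder(cols)
        rtree = tree_builder(rd, rtaxa)
        for bp in bipartitions(rtree):
            if bp in counts:
                counts[bp] += 1
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_set) - 1:
            continue
        key = side if ref not in side else all_set - side
        if key in counts:
            node.label = f"{100.0 * counts[key] / reps:g}"
    return tree
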