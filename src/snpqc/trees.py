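"""Neighbor-joining trees, newick I/O and strict tree comparison.

Trees are held as :class:`dendropy.Tree` objects and treated as unrooted
throughout. The NJ agglomeration is the classic Saitou-Nei algorithm with
two determinism rules: ties in the Q criterion are broken by the
lexicographically lowest pair of cluster representative labels (the
representative of a merged cluster is its smallest leaf label), and a
negative branch length is clamped to zero with the deficit transferred to
its sibling branch so the joined pair's total length is preserved.

"Strict" tree comparison counts exactly matching internal-edge
bipartitions (splits), ignoring branch lengths, and reports the
percentage of unshared splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .genotypes import GenotypeError

__all__ = [
    "TreeComparison",
    "neighbor_joining",
    "to_newick",
    "read_newick",
    "compare_trees",
    "tree_bipartitions",
    "path_length_matrix",
]


class NewickParseError(ValueError):
    """A newick string could not be parsed."""


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a distance matrix (>= 3 labels).

    Branch lengths for a joined pair (i, j) follow Saitou-Nei:
    ``l_i = d_ij/2 + (r_i - r_j) / (2 (m - 2))`` with ``l_j = d_ij - l_i``;
    negative lengths are clamped to 0 and the deficit moved to the sibling.
    On an additive matrix the output's path-length matrix reproduces the
    input exactly (up to floating-point error).
    """
    n = dm.n
    if n < 3:
        raise GenotypeError("neighbor_joining requires at least 3 labels")
    d = np.asarray(dm.values, dtype=float).copy()
    if np.any(d < 0):
        raise GenotypeError("distance matrix has negative entries")
    if np.isnan(d).any():
        raise GenotypeError("distance matrix has undefined entries")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # cluster representative = smallest leaf label
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        reps.append(label)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        # deterministic tie-break on representative-label pairs
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj

        # distances from the new node to every other active cluster
        new = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new
        d[:, i] = new
        d[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    # final three clusters join at the central (unrooted) node
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = tree.seed_node
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree as a single-line newick string."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(s: str) -> dendropy.Tree:
    """Parse a newick string; raises :class:`NewickParseError` on failure."""
    depth = 0
    for offset, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at offset {offset}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' in newick string")
    try:
        tree = dendropy.Tree.get(data=s, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Internal-edge bipartitions as canonical {side, complement} pairs.

    Only edges with at least two leaves on each side are counted (pendant
    edges split off a single leaf and are shared by all trees on the same
    leaf set).
    """
    all_leaves = frozenset(_leaf_labels(tree))
    n = len(all_leaves)
    splits: set[frozenset] = set()
    side_of: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            side_of[node] = frozenset({node.taxon.label})
        else:
            side = frozenset().union(*(side_of[c] for c in node.child_nodes()))
            side_of[node] = side
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset({side, all_leaves - side}))
    return splits


@dataclass(frozen=True)
class TreeComparison:
    """Strict (exact-bipartition) comparison of two trees."""

    n_internal_bipartitions_1: int
    n_internal_bipartitions_2: int
    n_shared: int
    dissimilarity_pct: float


def compare_trees(
    t1: dendropy.Tree, t2: dendropy.Tree, normalization: str = "max"
) -> TreeComparison:
    """Percentage of internal bipartitions not shared between two trees.

    ``dissimilarity_pct = 100 * (1 - shared / norm)`` where ``norm`` is the
    larger of the two internal-split counts (``normalization="max"``, the
    default), the smaller (``"min"``) or their mean (``"avg"``). Branch
    lengths and newick node ordering are ignored; the leaf sets must be
    identical.
    """
    leaves1, leaves2 = _leaf_labels(t1), _leaf_labels(t2)
    if leaves1 != leaves2:
        diff = sorted(leaves1 ^ leaves2)
        raise GenotypeError(f"trees have different leaf sets; symmetric difference: {diff}")
    s1 = tree_bipartitions(t1)
    s2 = tree_bipartitions(t2)
    shared = len(s1 & s2)
    if normalization == "max":
        norm = max(len(s1), len(s2))
    elif normalization == "min":
        norm = min(len(s1), len(s2))
    elif normalization == "avg":
        norm = 0.5 * (len(s1) + len(s2))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    pct = 0.0 if norm == 0 else 100.0 * (1.0 - shared / norm)
    return TreeComparison(
        n_internal_bipartitions_1=len(s1),
        n_internal_bipartitions_2=len(s2),
        n_shared=shared,
        dissimilarity_pct=pct,
    )


def path_length_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            v = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            out[i, j] = out[j, i] = v
    return out
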