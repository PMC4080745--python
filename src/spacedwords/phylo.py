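"""Neighbor-joining trees and Robinson-Foulds comparison.

Neighbor joining (Saitou-Nei) agglomerates a distance matrix into an
unrooted tree: at each step the pair minimizing the Q criterion

    Q(i, j) = (r - 2) d(i, j) - R_i - R_j

(with ``R_i`` the row sum over the ``r`` active nodes) is joined, branch
lengths assigned from the row sums, and the matrix reduced.  On an
additive matrix NJ recovers the generating tree exactly, branch lengths
included.  Ties in Q are broken by the lowest index pair so results are
identical across runs and platforms.

The Robinson-Foulds distance between two trees on the same leaves is the
size of the symmetric difference of their sets of non-trivial
bipartitions (the splits induced by internal edges); it is at most
``2 (n - 3)`` for binary trees.

Trees are held as :class:`PhyloTree`, a thin wrapper around a dendropy
tree providing split extraction, path-length matrices and Newick I/O.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "PhyloTree",
    "neighbor_joining",
    "robinson_foulds",
    "parse_newick",
    "read_newick",
]


def _sanitize_label(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


class PhyloTree:
    """An unrooted, Newick-serializable tree with labeled leaves."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = False
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(label is None for label in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._labels = tuple(sorted(labels))

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Leaf labels in sorted order."""
        return self._labels

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    # -- splits ---------------------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each as the side not holding the
        reference (lexicographically smallest) leaf."""
        all_leaves = set(self._labels)
        ref = self._labels[0]
        n = len(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[int, set[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = {node.taxon.label}
            else:
                s: set[str] = set()
                for child in node.child_nodes():
                    s |= below[id(child)]
                below[id(node)] = s
                if node is self._tree.seed_node:
                    continue
                if 2 <= len(s) <= n - 2:
                    side = s if ref not in s else all_leaves - s
                    splits.add(frozenset(side))
        return frozenset(splits)

    # -- distances ------------------------------------------------------

    def path_length_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        labels = self._labels
        index = {label: i for i, label in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))
        # accumulate pair distances bottom-up: for each node, paths that
        # cross it join leaf sets of distinct children
        depth: dict[int, dict[str, float]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                depth[id(node)] = {node.taxon.label: 0.0}
                continue
            merged: dict[str, float] = {}
            for child in node.child_nodes():
                blen = child.edge.length or 0.0
                sub = {l: d + blen for l, d in depth[id(child)].items()}
                for la, da in sub.items():
                    for lb, db in merged.items():
                        d = da + db
                        values[index[la], index[lb]] = d
                        values[index[lb], index[la]] = d
                merged.update(sub)
            depth[id(node)] = merged
        return DistanceMatrix(labels, values)

    # -- serialization --------------------------------------------------

    def to_newick(self) -> str:
        """Newick string; labels sanitized, branch lengths to 6 significant
        digits, no rooting annotation."""
        for taxon in self._tree.taxon_namespace:
            taxon.label = _sanitize_label(taxon.label)
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".6g",
            unquoted_underscores=True,
        )
        return text.strip() + "\n"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_leaves={self.n_leaves})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    if ";" not in text:
        raise ValueError("Newick text must be terminated by ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def neighbor_joining(
    matrix: DistanceMatrix, clamp_negative: bool = False
) -> PhyloTree:
    """Build an unrooted NJ tree from a distance matrix.

    Negative branch lengths (possible on non-additive input) are kept,
    with a warning, for PHYLIP-compatible behavior; ``clamp_negative``
    clamps them to zero instead.
    """
    labels = matrix.labels
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in labels:
        nodes.append(dendropy.Node(taxon=tns.new_taxon(label)))

    d = matrix.values.copy()
    active = list(range(n))
    saw_negative = False

    def attach(parent: dendropy.Node, child: dendropy.Node, blen: float) -> None:
        nonlocal saw_negative
        if blen < 0:
            saw_negative = True
            if clamp_negative:
                blen = 0.0
        parent.add_child(child)
        child.edge.length = float(blen)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin on the flattened matrix -> lowest (i, j) in row-major
        # order on ties, a deterministic tie-break
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        attach(parent, nodes[i], li)
        attach(parent, nodes[j], lj)
        nodes.append(parent)
        pidx = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            dn = 0.5 * (d[i, a] + d[j, a] - dij)
            d[pidx, a] = d[a, pidx] = dn
        active = [a for a in active if a not in (i, j)] + [pidx]

    root = dendropy.Node()
    if len(active) == 1:  # pragma: no cover - unreachable for n >= 2
        root = nodes[active[0]]
    elif len(active) == 2:
        i, j = active
        blen = d[i, j]
        attach(root, nodes[i], blen / 2.0)
        attach(root, nodes[j], blen / 2.0)
    else:
        i, j, k = active
        attach(root, nodes[i], 0.5 * (d[i, j] + d[i, k] - d[j, k]))
        attach(root, nodes[j], 0.5 * (d[i, j] + d[j, k] - d[i, k]))
        attach(root, nodes[k], 0.5 * (d[i, k] + d[j, k] - d[i, j]))

    if saw_negative and not clamp_negative:
        warnings.warn(
            "neighbor joining produced negative branch lengths "
            "(non-additive input); they are retained",
            stacklevel=2,
        )
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    return PhyloTree(tree)


def robinson_foulds(
    t1: PhyloTree, t2: PhyloTree, normalized: bool = False
) -> int | float:
    """Robinson-Foulds distance: symmetric difference of non-trivial splits.

    With ``normalized=True`` the count is divided by ``2 (n - 3)``, the
    maximum for two binary trees on ``n`` leaves.
    """
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError(
            "trees have different leaf sets: "
            f"{sorted(set(t1.leaf_labels) ^ set(t2.leaf_labels))}"
        )
    rf = len(t1.splits() ^ t2.splits())
    if normalized:
        n = t1.n_leaves
        if n < 4:
            return 0.0
        return rf / (2 * (n - 3))
    return rf
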