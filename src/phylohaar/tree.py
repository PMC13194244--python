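"""Planted binary trees: Newick I/O, depths, path lengths, and balance statistics.

A *planted* tree is a rooted tree whose root (written ``o``) has exactly one
child; the edge below the root (the "planted edge") contributes shared
covariance to every leaf.  All downstream machinery (Haar-like wavelets,
covariance sparsification, the Haar-like distance) assumes this shape, with
every non-root interior node binary and children ordered left-to-right.
Leaves are ranked by the order in which they are met in a postorder
traversal, i.e. their left-to-right order.

Two depth conventions coexist in the literature: counting the planted edge
(a leaf's edge-distance to ``o``) or not (distance to the child of ``o``,
under which a one-leaf tree has depth 0).  They differ by exactly one per
leaf; functions here take an explicit ``convention`` argument.
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "PlantedTree",
    "TreeError",
    "load_newick",
    "leaf_depths",
    "external_path_length",
    "subtree_leaf_counts",
    "minor_split_summary",
    "PLANTED",
    "UNPLANTED",
]

#: depth convention flags
PLANTED = "planted"
UNPLANTED = "unplanted"


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


def _check_convention(convention: str) -> str:
    if convention not in (PLANTED, UNPLANTED):
        raise ValueError(f"unknown depth convention: {convention!r}")
    return convention


class PlantedTree:
    """Rooted binary tree with a degree-1 planted root and ordered children.

    Nodes are integer ids into parallel arrays.  ``left``/``right`` are -1
    for leaves; the root stores its single child in ``left``.
    ``edge_length[v]`` is the length of the edge from ``v`` to its parent
    (0.0 and unused at the root itself; the planted edge is the root
    child's entry).

    Parameters
    ----------
    parent, left, right : sequences of int
        Node adjacency; -1 denotes "absent".
    edge_length : sequence of float
        Nonnegative branch lengths, indexed like the other arrays.
    root : int
        Id of the planted root.
    names : list of str or None
        Optional leaf labels, indexed by node id.
    """

    __slots__ = (
        "parent",
        "left",
        "right",
        "edge_length",
        "root",
        "names",
        "_postorder",
        "_leaf_order",
        "_leaf_rank",
        "_lo",
        "_hi",
    )

    def __init__(self, parent, left, right, edge_length, root, names=None, *, validate=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64)
        self.root = int(root)
        self.names = names
        self._postorder = None
        self._leaf_order = None
        self._leaf_rank = None
        self._lo = None
        self._hi = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #

    def _validate(self) -> None:
        n_nodes = len(self.parent)
        if not (len(self.left) == len(self.right) == len(self.edge_length) == n_nodes):
            raise TreeError("node arrays must have equal length")
        if n_nodes == 0:
            raise TreeError("empty tree")
        if self.parent[self.root] != -1:
            raise TreeError("root must have no parent")
        if self.left[self.root] < 0 or self.right[self.root] >= 0:
            raise TreeError("planted root must have exactly one child")
        for v in range(n_nodes):
            if v == self.root:
                continue
            l, r = self.left[v], self.right[v]
            if (l < 0) != (r < 0):
                raise TreeError(f"node {v} is not binary (one child)")
            if self.edge_length[v] < 0:
                raise TreeError(f"negative edge length at node {v}")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    @property
    def top(self) -> int:
        """The single child of the planted root."""
        return int(self.left[self.root])

    def is_leaf(self, v: int) -> bool:
        return self.left[v] < 0

    @property
    def postorder(self) -> np.ndarray:
        """All node ids in postorder (children before parents, left first)."""
        if self._postorder is None:
            order = np.empty(self.n_nodes, dtype=np.int64)
            k = 0
            stack = [(self.root, False)]
            while stack:
                v, expanded = stack.pop()
                if expanded or self.left[v] < 0:
                    order[k] = v
                    k += 1
                    continue
                stack.append((v, True))
                if self.right[v] >= 0:
                    stack.append((int(self.right[v]), False))
                stack.append((int(self.left[v]), False))
            if k != self.n_nodes:
                raise TreeError("disconnected node records")
            self._postorder = order
        return self._postorder

    @property
    def leaf_order(self) -> np.ndarray:
        """Leaf ids in left-to-right (postorder) order."""
        if self._leaf_order is None:
            po = self.postorder
            self._leaf_order = po[self.left[po] < 0]
        return self._leaf_order

    @property
    def leaf_rank(self) -> np.ndarray:
        """Node id -> leaf rank (or -1 for non-leaves)."""
        if self._leaf_rank is None:
            rank = np.full(self.n_nodes, -1, dtype=np.int64)
            rank[self.leaf_order] = np.arange(self.n_leaves)
            self._leaf_rank = rank
        return self._leaf_rank

    def _intervals(self):
        """Per-node half-open leaf-rank interval [lo, hi) of the subtree."""
        if self._lo is None:
            lo = np.empty(self.n_nodes, dtype=np.int64)
            hi = np.empty(self.n_nodes, dtype=np.int64)
            rank = self.leaf_rank
            for v in self.postorder:
                if self.left[v] < 0:
                    lo[v] = rank[v]
                    hi[v] = rank[v] + 1
                elif self.right[v] < 0:  # planted root
                    lo[v] = lo[self.left[v]]
                    hi[v] = hi[self.left[v]]
                else:
                    lo[v] = lo[self.left[v]]
                    hi[v] = hi[self.right[v]]
            self._lo, self._hi = lo, hi
        return self._lo, self._hi

    @property
    def interior_nodes(self) -> np.ndarray:
        """Non-root interior (split) nodes, in postorder."""
        po = self.postorder
        return po[(self.left[po] >= 0) & (po != self.root)]

    def depths(self, convention: str = PLANTED) -> np.ndarray:
        """Edge-depth of every node under the given convention.

        ``PLANTED`` counts edges to the planted root; ``UNPLANTED`` counts
        edges to the root's child (so the root child has depth 0 and the
        root itself -1).
        """
        _check_convention(convention)
        depth = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.postorder[::-1]:
            if v == self.root:
                depth[v] = 0
            else:
                depth[v] = depth[self.parent[v]] + 1
        if convention == UNPLANTED:
            depth -= 1
        return depth

    def weighted_depths(self) -> np.ndarray:
        """Sum of branch lengths from each node up to the planted root."""
        wd = np.zeros(self.n_nodes, dtype=np.float64)
        for v in self.postorder[::-1]:
            if v != self.root:
                wd[v] = wd[self.parent[v]] + self.edge_length[v]
        return wd

    # ------------------------------------------------------------------ #
    # Newick
    # ------------------------------------------------------------------ #

    def leaf_name(self, v: int) -> str:
        if self.names is not None and self.names[v]:
            return self.names[v]
        return f"L{int(self.leaf_rank[v]) + 1}"

    def to_newick(self) -> str:
        """Serialize to Newick; the planted-edge length becomes the root
        branch length. Branch lengths are written to 10 significant digits."""
        out = io.StringIO()
        # iterative in-order emission to survive deep caterpillars
        stack = [(self.top, 0)]
        while stack:
            v, state = stack.pop()
            if self.left[v] < 0:
                out.write(self.leaf_name(v))
                out.write(f":{self.edge_length[v]:.10g}")
                continue
            if state == 0:
                out.write("(")
                stack.append((v, 1))
                stack.append((int(self.left[v]), 0))
            elif state == 1:
                out.write(",")
                stack.append((v, 2))
                stack.append((int(self.right[v]), 0))
            else:
                out.write(f"):{self.edge_length[v]:.10g}")
        out.write(";")
        return out.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PlantedTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------- #
# parsing
# ---------------------------------------------------------------------- #


def load_newick(text: str, default_planted_length: float = 0.0) -> PlantedTree:
    """Parse a Newick string into a :class:`PlantedTree`.

    Missing branch lengths default to 1.0.  A branch length on the
    outermost group, when present, becomes the planted-edge length;
    otherwise ``default_planted_length`` is used.  Multifurcations are
    resolved into a left-to-right cascade of zero-length edges, which
    leaves the phylogenetic covariance matrix unchanged.  Unifurcations
    are contracted (their lengths summed).
    """
    if default_planted_length < 0:
        raise ValueError("default_planted_length must be nonnegative")
    if not text or not text.strip() or text.strip() in (";", "();"):
        raise TreeError("empty tree")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports line/column in the message
        raise TreeError(f"malformed Newick: {exc}") from exc

    parent: list[int] = []
    left: list[int] = []
    right: list[int] = []
    elen: list[float] = []
    names: list[str | None] = []

    def new_node(length: float, name: str | None = None) -> int:
        parent.append(-1)
        left.append(-1)
        right.append(-1)
        elen.append(length)
        names.append(name)
        return len(parent) - 1

    def edge_len(dnode) -> float:
        return 1.0 if dnode.edge.length is None else float(dnode.edge.length)

    def label(dnode) -> str | None:
        if dnode.taxon is not None and dnode.taxon.label:
            return str(dnode.taxon.label)
        if dnode.label:
            return str(dnode.label)
        return None

    seed = dtree.seed_node
    if seed.is_leaf() and label(seed) is None:
        raise TreeError("empty tree")

    def cascade(children: list[int]) -> int:
        # fold right-to-left so that (c1,c2,...,ck) becomes
        # (c1,(c2,(...,ck))) with zero-length connecting edges
        cur = children[-1]
        for cl in children[-2::-1]:
            node = new_node(0.0)
            left[node], right[node] = cl, cur
            parent[cl] = parent[cur] = node
            cur = node
        return cur

    index: dict = {}
    for dnode in dtree.postorder_node_iter():
        if dnode is seed:
            continue
        kids = dnode.child_nodes()
        if not kids:
            index[dnode] = new_node(edge_len(dnode), label(dnode))
        elif len(kids) == 1:
            # unifurcation: contract, accumulating length
            child = index[kids[0]]
            elen[child] += edge_len(dnode)
            index[dnode] = child
        else:
            cur = cascade([index[k] for k in kids])
            elen[cur] = edge_len(dnode)
            index[dnode] = cur

    # The outermost group's branch length, when present, is the planted-edge
    # length; otherwise the caller-supplied default applies.  A unifurcating
    # seed ("pre-planted" Newick) contributes its child's length as well.
    seed_kids = seed.child_nodes()
    seed_len = None if seed.edge.length is None else float(seed.edge.length)
    if not seed_kids:
        top = new_node(default_planted_length if seed_len is None else seed_len, label(seed))
    elif len(seed_kids) == 1:
        top = index[seed_kids[0]]
        if seed_len is not None:
            elen[top] += seed_len
    else:
        top = cascade([index[k] for k in seed_kids])
        elen[top] = default_planted_length if seed_len is None else seed_len

    root = new_node(0.0)
    left[root] = top
    parent[top] = root
    tree = PlantedTree(parent, left, right, elen, root, names)
    if np.any(tree.edge_length[np.arange(tree.n_nodes) != root] < 0):
        raise TreeError("negative branch length")
    return tree


# ---------------------------------------------------------------------- #
# statistics
# ---------------------------------------------------------------------- #


def leaf_depths(tree: PlantedTree, convention: str = PLANTED) -> np.ndarray:
    """Edge-depth of each leaf, in leaf (left-to-right) order."""
    return tree.depths(convention)[tree.leaf_order]


def external_path_length(tree: PlantedTree, convention: str = PLANTED) -> int:
    """Sum of leaf edge-depths; the two conventions differ by ``n_leaves``."""
    return int(leaf_depths(tree, convention).sum())


def subtree_leaf_counts(tree: PlantedTree) -> np.ndarray:
    """Number of descendant leaves per node id (leaves map to 1)."""
    lo, hi = tree._intervals()
    return hi - lo


def minor_split_summary(tree: PlantedTree) -> pd.DataFrame:
    """Median minor-split size per clade size.

    For every split of a clade of size ``m`` into sub-clades of sizes
    ``(i, m - i)``, records ``min(i, m - i)``; returns the per-``m`` median
    (the tree-balance diagnostic distinguishing square-root from
    logarithmic balance profiles), with the split count per clade size.
    """
    counts = subtree_leaf_counts(tree)
    rows = []
    for v in tree.interior_nodes:
        i, j = counts[tree.left[v]], counts[tree.right[v]]
        rows.append((int(i + j), int(min(i, j))))
    if not rows:
        return pd.DataFrame(columns=["clade_size", "median_minor", "n_splits"]).astype(
            {"clade_size": int, "median_minor": float, "n_splits": int}
        )
    df = pd.DataFrame(rows, columns=["clade_size", "minor"])
    out = (
        df.groupby("clade_size")["minor"]
        .agg(median_minor="median", n_splits="size")
        .reset_index()
        .sort_values("clade_size", ascending=False, ignore_index=True)
    )
    return out
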