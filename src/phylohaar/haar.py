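"""Haar-like wavelets and sparse pseudo-diagonalization of the
phylogenetic covariance matrix.

Each interior node ``v`` of a planted binary tree carries a wavelet that is
constant and positive on the leaves of the left subtree, constant and
negative on the right, zero elsewhere, with coefficients

    c-(v) = sqrt(|L(v+)| / (|L(v-)| |L(v)|)),
    c+(v) = sqrt(|L(v-)| / (|L(v+)| |L(v)|)),

so every wavelet has unit norm and (away from the root) zero sum; the root
carries the constant vector 1/sqrt(|L|).  The covariance matrix
``C(i,j) = sum of branch lengths from lca(i,j) up to the planted root`` is
ultrametric, and in the wavelet basis ``Phi^T C Phi`` has a structural zero
at every pair of wavelets with disjoint supports.  The transform is
computed here without ever materializing ``C``, from per-subtree second
moments of trace lengths ``l(e) |L(e)|^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import PLANTED, PlantedTree, external_path_length, subtree_leaf_counts

__all__ = [
    "HaarBasis",
    "SparseTransform",
    "build_basis",
    "covariance_dense",
    "transform",
    "sparsity_stats",
    "sparsity_bound",
]


@dataclass
class HaarBasis:
    """Haar-like wavelets stored by leaf-rank support intervals.

    Wavelet ``k`` is supported on leaf ranks ``[lo[k], hi[k])`` and equals
    ``+coef_left[k]`` on ``[lo[k], mid[k])`` and ``-coef_right[k]`` on
    ``[mid[k], hi[k])``.  Index 0 is the root (constant) wavelet, encoded
    with ``mid == hi`` and ``coef_left = 1/sqrt(n)``; indices 1.. follow
    the postorder of the non-root interior nodes.
    """

    tree: PlantedTree
    nodes: np.ndarray  # wavelet index -> tree node id (nodes[0] = planted root)
    lo: np.ndarray
    mid: np.ndarray
    hi: np.ndarray
    coef_left: np.ndarray
    coef_right: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves

    @property
    def n_wavelets(self) -> int:
        return len(self.nodes)

    def wavelet_index(self, node: int) -> int:
        """Wavelet index of a tree node (root or interior)."""
        hits = np.flatnonzero(self.nodes == node)
        if len(hits) == 0:
            raise KeyError(f"node {node} carries no wavelet")
        return int(hits[0])

    def dense(self) -> np.ndarray:
        """Materialize the basis matrix Phi (n_leaves x n_wavelets)."""
        n = self.n_leaves
        phi = np.zeros((n, self.n_wavelets))
        for k in range(self.n_wavelets):
            phi[self.lo[k] : self.mid[k], k] = self.coef_left[k]
            phi[self.mid[k] : self.hi[k], k] = -self.coef_right[k]
        return phi

    def coordinates(self, f: np.ndarray) -> np.ndarray:
        """All wavelet coordinates of leaf vector(s) ``f`` in O(n) per vector.

        ``f`` has leaf rank along its last axis; a cumulative-sum pass
        yields every block sum, so no per-wavelet dot products are needed.
        """
        f = np.asarray(f, dtype=np.float64)
        cs = np.zeros(f.shape[:-1] + (f.shape[-1] + 1,))
        np.cumsum(f, axis=-1, out=cs[..., 1:])
        return self.coef_left * (cs[..., self.mid] - cs[..., self.lo]) - self.coef_right * (
            cs[..., self.hi] - cs[..., self.mid]
        )

    def reconstruct(self, coords: np.ndarray, keep=None) -> np.ndarray:
        """Leaf vector ``sum_k coords[k] * phi_k`` over ``keep`` (default all),
        accumulated sparsely over support intervals."""
        out = np.zeros(self.n_leaves)
        indices = range(self.n_wavelets) if keep is None else np.asarray(keep, dtype=int)
        for k in indices:
            c = coords[k]
            if c == 0.0:
                continue
            out[self.lo[k] : self.mid[k]] += c * self.coef_left[k]
            out[self.mid[k] : self.hi[k]] -= c * self.coef_right[k]
        return out


def build_basis(tree: PlantedTree) -> HaarBasis:
    """Construct the Haar-like basis of a planted binary tree."""
    lo, hi = tree._intervals()
    counts = subtree_leaf_counts(tree)
    interior = tree.interior_nodes
    nodes = np.concatenate(([tree.root], interior))
    n = tree.n_leaves

    k = len(nodes)
    blo = np.empty(k, dtype=np.int64)
    bmid = np.empty(k, dtype=np.int64)
    bhi = np.empty(k, dtype=np.int64)
    cl = np.empty(k)
    cr = np.empty(k)

    blo[0], bmid[0], bhi[0] = 0, n, n
    cl[0], cr[0] = 1.0 / np.sqrt(n), 0.0
    if k > 1:
        l, r = tree.left[interior], tree.right[interior]
        nl, nr = counts[l].astype(float), counts[r].astype(float)
        nv = nl + nr
        blo[1:], bmid[1:], bhi[1:] = lo[interior], lo[r], hi[interior]
        cl[1:] = np.sqrt(nr / (nl * nv))
        cr[1:] = np.sqrt(nl / (nr * nv))
    return HaarBasis(tree, nodes, blo, bmid, bhi, cl, cr)


def covariance_dense(tree: PlantedTree, cap: int = 2048) -> np.ndarray:
    """The dense phylogenetic covariance matrix over leaves.

    ``C(i, j)`` is the total branch length from the least common ancestor
    of leaves ``i`` and ``j`` up to and including the planted edge;
    the diagonal is each leaf's weighted planted depth.  Guarded by a size
    cap: beyond it, use :func:`transform`, which never forms ``C``.
    """
    n = tree.n_leaves
    if n > cap:
        raise ValueError(
            f"dense covariance for {n} leaves exceeds cap={cap}; use transform() instead"
        )
    wd = tree.weighted_depths()
    lo, hi = tree._intervals()
    C = np.zeros((n, n))
    rank = tree.leaf_rank
    for v in tree.leaf_order:
        C[rank[v], rank[v]] = wd[v]
    for v in tree.interior_nodes:
        l, r = tree.left[v], tree.right[v]
        C[lo[l] : hi[l], lo[r] : hi[r]] = wd[v]
        C[lo[r] : hi[r], lo[l] : hi[l]] = wd[v]
    return C


@dataclass
class SparseTransform:
    """Coordinate-form representation of ``Phi^T C Phi``.

    ``diagonal[k]`` holds lambda for wavelet ``k`` (basis index order).
    ``rows/cols/values`` list the structurally-nonzero strictly-upper
    entries, ``rows[j]`` being the ancestor-side wavelet; the matrix is
    symmetric so each listed pair implies its mirror.  Every pair absent
    from the structural set is exactly zero.
    """

    basis: HaarBasis
    diagonal: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray

    @property
    def n(self) -> int:
        """Matrix order (= number of leaves = number of wavelets)."""
        return self.basis.n_wavelets

    @property
    def n_structural_pairs(self) -> int:
        """Unordered structurally-nonzero off-diagonal pairs."""
        return len(self.values)

    def to_dense(self) -> np.ndarray:
        m = np.diag(self.diagonal.copy())
        m[self.rows, self.cols] += self.values
        m[self.cols, self.rows] += self.values
        return m

    def trace(self) -> float:
        return float(self.diagonal.sum())


def transform(tree: PlantedTree) -> SparseTransform:
    """Compute ``Phi^T C Phi`` exploiting nested supports; never forms C.

    With ``S(w)`` the sum of ``l(e) |L(e)|^2`` over the edges in the
    subtree hanging from ``w`` (including w's parent edge),

        lambda_root = S(top) / n,
        lambda_v    = c-(v)^2 S(v-) + c+(v)^2 S(v+),
        entry(u, v) = phi_u[block of L(v)] * (c-(v) S(v-) - c+(v) S(v+))

    for ``u`` a strict ancestor of ``v`` or the root.  Runtime is
    O(n + number of structural pairs), the latter bounded by the sum of
    interior-node depths.
    """
    basis = build_basis(tree)
    counts = subtree_leaf_counts(tree)
    n = tree.n_leaves

    # subtree second moments of trace length
    S = np.zeros(tree.n_nodes)
    for v in tree.postorder:
        if v == tree.root:
            continue
        S[v] = tree.edge_length[v] * float(counts[v]) ** 2
        if tree.left[v] >= 0:
            S[v] += S[tree.left[v]] + S[tree.right[v]]

    k = basis.n_wavelets
    diag = np.empty(k)
    diag[0] = S[tree.top] / n
    interior = basis.nodes[1:]
    wav_of_node = np.full(tree.n_nodes, -1, dtype=np.int64)
    wav_of_node[basis.nodes] = np.arange(k)

    d = np.zeros(k)  # c-(v) S(v-) - c+(v) S(v+), the ancestor-interaction factor
    if k > 1:
        l, r = tree.left[interior], tree.right[interior]
        diag[1:] = basis.coef_left[1:] ** 2 * S[l] + basis.coef_right[1:] ** 2 * S[r]
        d[1:] = basis.coef_left[1:] * S[l] - basis.coef_right[1:] * S[r]

    rows, cols, vals = [], [], []
    root_val = 1.0 / np.sqrt(n)
    for kv in range(1, k):
        v = interior[kv - 1]
        child = v
        u = int(tree.parent[v])
        while u != tree.root:
            ku = wav_of_node[u]
            phi_u = basis.coef_left[ku] if tree.left[u] == child else -basis.coef_right[ku]
            rows.append(ku)
            cols.append(kv)
            vals.append(phi_u * d[kv])
            child = u
            u = int(tree.parent[u])
        rows.append(0)
        cols.append(kv)
        vals.append(root_val * d[kv])

    return SparseTransform(
        basis,
        diag,
        np.asarray(rows, dtype=np.int64),
        np.asarray(cols, dtype=np.int64),
        np.asarray(vals, dtype=np.float64),
    )


def sparsity_stats(st: SparseTransform, mode: str = "structural", tol: float = 1e-12) -> dict:
    """Vanishing-entry fractions of the transformed matrix.

    ``structural`` counts as vanishing every off-diagonal pair outside the
    nested-support set; ``numerical`` additionally counts stored entries
    with ``|value| <= tol``.  Returns the off-diagonal fraction ``xi``
    (vanishing / (n^2 - n)) together with the all-entries variant and the
    complementary nonzero fraction.
    """
    if mode not in ("structural", "numerical"):
        raise ValueError(f"unknown mode: {mode!r}")
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    n = st.n
    off_total = n * n - n
    nonzero = 2 * st.n_structural_pairs
    if mode == "numerical":
        nonzero -= 2 * int(np.count_nonzero(np.abs(st.values) <= tol))
    if off_total == 0:
        xi = 1.0
    else:
        xi = (off_total - nonzero) / off_total
    # all-entries variant divides by n^2; the diagonal is never counted
    # as vanishing (lambda >= 0 and generically > 0)
    xi_all = (off_total - nonzero) / (n * n)
    return {
        "xi": xi,
        "xi_all_entries": xi_all,
        "nonzero_offdiag_fraction": 0.0 if off_total == 0 else nonzero / off_total,
        "n": n,
        "mode": mode,
    }


def sparsity_bound(tree: PlantedTree) -> float:
    """Guaranteed upper bound on the *non*-vanishing off-diagonal fraction:

        1 - xi  <=  2 (EPL + 1) / n^2  -  3 / n,

    with EPL in the planted convention.  Values >= 1 are vacuous (highly
    imbalanced trees); small values certify pseudo-diagonalization.
    """
    n = tree.n_leaves
    if n < 2:
        raise ValueError("sparsity_bound requires n >= 2")
    epl = external_path_length(tree, PLANTED)
    return 2.0 * (epl + 1) / n**2 - 3.0 / n
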