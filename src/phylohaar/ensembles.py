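"""Random binary tree ensembles: critical beta-splitting and uniform.

The critical beta-splitting model recursively splits a clade of ``n`` leaves
into ordered sub-clades of sizes ``(i, n - i)`` with probability

    q(n, i) = n / (2 h_{n-1}) * 1 / (i (n - i)),    0 < i < n,

where ``h_k`` is the k-th harmonic number.  Its median minor-split size
grows like sqrt(n), matching real-world phylogenies; the uniform model
(uniform over ordered binary shapes, i.e. the Catalan split law) produces
markedly less balanced trees whose minor splits grow only logarithmically.

A small-n exhaustive shape enumerator in exact rational arithmetic serves
as the oracle for sampler and moment-recursion tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Callable, Union

import numpy as np

from .tree import PlantedTree

__all__ = [
    "CRITICAL_BETA",
    "UNIFORM",
    "EnsembleConfig",
    "split_pmf",
    "split_pmf_exact",
    "sample_split",
    "sample_tree",
    "exact_shape_distribution",
    "shape_epl",
    "epl_moments_from_shapes",
]

CRITICAL_BETA = "critical_beta"
UNIFORM = "uniform"

# growing cache of harmonic numbers h_0..h_k (float) for inverse-CDF sampling
_HARMONIC = np.zeros(2, dtype=np.float64)
_HARMONIC[1] = 1.0


def _harmonics(n: int) -> np.ndarray:
    """h_0..h_n as a cached float array."""
    global _HARMONIC
    if len(_HARMONIC) <= n:
        m = max(n + 1, 2 * len(_HARMONIC))
        ext = np.empty(m, dtype=np.float64)
        k = len(_HARMONIC)
        ext[:k] = _HARMONIC
        ext[k:] = 1.0 / np.arange(k, m)
        np.cumsum(ext[k - 1 :], out=ext[k - 1 :])
        _HARMONIC = ext
    return _HARMONIC[: n + 1]


@lru_cache(maxsize=None)
def _harmonic_exact(n: int) -> Fraction:
    return sum((Fraction(1, k) for k in range(1, n + 1)), Fraction(0))


def _log_catalan(k: int) -> float:
    return math.lgamma(2 * k + 1) - 2.0 * math.lgamma(k + 1) - math.log(k + 1)


@lru_cache(maxsize=None)
def _catalan_exact(k: int) -> int:
    return math.comb(2 * k, k) // (k + 1)


def _check_law(law: str) -> str:
    if law not in (CRITICAL_BETA, UNIFORM):
        raise ValueError(f"unknown split law: {law!r}")
    return law


def split_pmf(law: str, n: int) -> np.ndarray:
    """Split-size pmf over ``i = 1..n-1`` as a float vector.

    ``critical_beta``: q(n,i) = n / (2 h_{n-1} i (n-i)).
    ``uniform``: q(n,i) = Cat(i-1) Cat(n-i-1) / Cat(n-1), the split law of
    the uniform distribution over ordered binary shapes.
    """
    _check_law(law)
    if n < 2:
        raise ValueError("split_pmf requires n >= 2")
    i = np.arange(1, n)
    if law == CRITICAL_BETA:
        h = _harmonics(n - 1)[n - 1]
        q = n / (2.0 * h * i * (n - i))
    else:
        logs = np.array([_log_catalan(int(j - 1)) + _log_catalan(int(n - j - 1)) for j in i])
        logs -= _log_catalan(n - 1)
        q = np.exp(logs)
    return q / q.sum()


def split_pmf_exact(law: str, n: int) -> list[Fraction]:
    """Exact rational split pmf (small n; used by the enumeration oracle)."""
    _check_law(law)
    if n < 2:
        raise ValueError("split_pmf requires n >= 2")
    if law == CRITICAL_BETA:
        h = _harmonic_exact(n - 1)
        return [Fraction(n, 2) / (h * i * (n - i)) for i in range(1, n)]
    cat = _catalan_exact(n - 1)
    return [Fraction(_catalan_exact(i - 1) * _catalan_exact(n - i - 1), cat) for i in range(1, n)]


def sample_split(law: str, n: int, rng: np.random.Generator) -> int:
    """Draw a left-clade size from the split law.

    The critical law is sampled exactly through the mixture identity
    1/(i(n-i)) = (1/i + 1/(n-i)) / n: draw J with P(J=j) proportional to
    1/j by inverse-CDF against cached harmonic numbers, then return J or
    n - J with a fair coin.  The uniform law is drawn by inverse-CDF on
    its Catalan pmf.
    """
    _check_law(law)
    if n < 2:
        raise ValueError("sample_split requires n >= 2")
    if n == 2:
        return 1
    if law == CRITICAL_BETA:
        h = _harmonics(n - 1)
        u = rng.random() * h[n - 1]
        j = int(np.searchsorted(h[1:n], u))  # smallest j with h_{j+1} > u, 0-based
        j += 1
        if rng.random() < 0.5:
            return j
        return n - j
    q = split_pmf(UNIFORM, n)
    return int(np.searchsorted(np.cumsum(q), rng.random())) + 1


@dataclass
class EnsembleConfig:
    """Simulation parameters for :func:`sample_tree`.

    ``edge_lengths`` is ``"unit"``, ``"exponential"`` (mean ``1/rate``), or
    a callable ``f(rng, size) -> array``; it is applied to every edge
    including the planted one.
    """

    n: int
    seed: int | None = None
    law: str = CRITICAL_BETA
    edge_lengths: Union[str, Callable] = "unit"
    rate: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        _check_law(self.law)


def sample_tree(cfg: EnsembleConfig, rng: np.random.Generator | None = None) -> PlantedTree:
    """Simulate a planted binary tree by recursive random splitting.

    Deterministic given ``cfg.seed`` (or a supplied generator); the
    left-to-right leaf order is the construction order.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    n_nodes = 2 * n  # n leaves, n-1 splits, 1 planted root
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    nxt = 0

    def new_node(par: int) -> int:
        nonlocal nxt
        parent[nxt] = par
        nxt += 1
        return nxt - 1

    root = new_node(-1)
    top = new_node(root)
    left[root] = top
    stack = [(n, top)]
    while stack:
        size, v = stack.pop()
        if size == 1:
            continue
        i = sample_split(cfg.law, size, rng)
        l = new_node(v)
        r = new_node(v)
        left[v], right[v] = l, r
        # depth-first, left branch first, so leaf ids increase left-to-right
        stack.append((size - i, r))
        stack.append((i, l))

    if cfg.edge_lengths == "unit":
        elen = np.ones(n_nodes, dtype=np.float64)
    elif cfg.edge_lengths == "exponential":
        elen = rng.exponential(1.0 / cfg.rate, size=n_nodes)
    elif callable(cfg.edge_lengths):
        elen = np.asarray(cfg.edge_lengths(rng, n_nodes), dtype=np.float64)
    else:
        raise ValueError(f"unknown edge length rule: {cfg.edge_lengths!r}")
    elen[root] = 0.0
    return PlantedTree(parent, left, right, elen, root)


# ---------------------------------------------------------------------- #
# exhaustive small-n oracle
# ---------------------------------------------------------------------- #

MAX_ENUMERATION = 12


def exact_shape_distribution(law: str, n: int) -> list[tuple[object, Fraction]]:
    """Enumerate all ordered binary shapes of ``n`` leaves with their exact
    probabilities under the split law.

    Shapes are nested tuples: a leaf is ``1`` and an internal clade is
    ``(left_shape, right_shape)``.  Probabilities are rational and sum to
    one exactly.  Refuses ``n`` beyond a small enumeration cap (the number
    of shapes is the (n-1)-st Catalan number).
    """
    _check_law(law)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_ENUMERATION:
        raise ValueError(f"refusing to enumerate n={n} > {MAX_ENUMERATION} (Catalan blow-up)")

    @lru_cache(maxsize=None)
    def rec(m: int):
        if m == 1:
            return ((1, Fraction(1)),)
        q = split_pmf_exact(law, m)
        out = []
        for i in range(1, m):
            for ls, lp in rec(i):
                for rs, rp in rec(m - i):
                    out.append(((ls, rs), q[i - 1] * lp * rp))
        return tuple(out)

    return list(rec(n))


def shape_epl(shape) -> int:
    """External path length of a shape, unplanted convention (one leaf -> 0)."""
    n, epl = _shape_size_epl(shape)
    return epl


def _shape_size_epl(shape) -> tuple[int, int]:
    if shape == 1:
        return 1, 0
    ln, lepl = _shape_size_epl(shape[0])
    rn, repl = _shape_size_epl(shape[1])
    # descending one level adds 1 to every leaf depth
    return ln + rn, lepl + repl + ln + rn


def epl_moments_from_shapes(law: str, n: int) -> dict[str, Fraction]:
    """Exact E(EPL), E(EPL^2) and Var(EPL) (unplanted) by enumeration."""
    dist = exact_shape_distribution(law, n)
    m1 = sum((p * shape_epl(s) for s, p in dist), Fraction(0))
    m2 = sum((p * shape_epl(s) ** 2 for s, p in dist), Fraction(0))
    return {"mean": m1, "second": m2, "var": m2 - m1 * m1}
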