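"""Synthetic paired OTU samples for calibration and power studies.

The generator emulates the permutation test's sampling model: reads from
each environment are i.i.d. draws from a fixed leaf composition, so a
sample of depth ``|a|`` is multinomial.  Under the null the two
environments share one composition; under the alternative a mass ``eps``
is moved across a chosen split (from the right leaf block to the left) in
environment ``a`` only, leaving every other split's block means untouched
in expectation.  Note that pooled without-replacement resampling is the
*test's* device, not the data model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import AbundanceSample
from .haar import build_basis
from .tree import PlantedTree

__all__ = ["SyntheticSpec", "synthetic_pair", "shifted_composition"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic sample pair.

    ``composition`` defaults to a symmetric Dirichlet(1) draw over the
    leaves.  ``effect_node`` is a tree node id (an interior split) and
    ``effect_size`` the probability mass moved from its right to its left
    leaf block in environment ``a``; 0 or ``None`` gives the null.
    """

    tree: PlantedTree
    composition: np.ndarray | None = None
    depth_a: int = 10_000
    depth_b: int = 10_000
    effect_node: int | None = None
    effect_size: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.depth_a < 1 or self.depth_b < 1:
            raise ValueError("sample depths must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.composition is not None:
            p = np.asarray(self.composition, dtype=np.float64)
            if p.shape != (self.tree.n_leaves,) or np.any(p < 0):
                raise ValueError("composition must be a nonnegative leaf vector")
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("composition must sum to 1")
            self.composition = p


def shifted_composition(
    tree: PlantedTree, base: np.ndarray, node: int, eps: float
) -> np.ndarray:
    """Move mass ``eps`` across the split at ``node``: the right leaf block
    is scaled down by ``eps`` in total, the left block up, proportionally
    within each block; the result still sums to one."""
    basis = build_basis(tree)
    k = basis.wavelet_index(int(node))
    if k == 0:
        raise ValueError("the root carries no split; pick an interior node")
    lo, mid, hi = basis.lo[k], basis.mid[k], basis.hi[k]
    p = np.asarray(base, dtype=np.float64).copy()
    m_left = p[lo:mid].sum()
    m_right = p[mid:hi].sum()
    if eps == 0.0:
        return p
    if eps > m_right:
        raise ValueError(f"effect_size {eps} exceeds right-block mass {m_right:.4g}")
    if m_left == 0.0:
        raise ValueError("left block has zero mass; nothing to scale up")
    p[lo:mid] *= (m_left + eps) / m_left
    p[mid:hi] *= (m_right - eps) / m_right
    return p


def synthetic_pair(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AbundanceSample, AbundanceSample, dict]:
    """Draw a pair of multinomial samples and a truth record.

    ``a`` is drawn from the (possibly shifted) composition, ``b`` from the
    base composition; the truth record carries the base composition and
    the perturbed node (or None).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.tree.n_leaves
    base = spec.composition
    if base is None:
        base = rng.dirichlet(np.ones(n))
    if spec.effect_node is not None and spec.effect_size > 0:
        p_a = shifted_composition(spec.tree, base, spec.effect_node, spec.effect_size)
    else:
        p_a = base
    a = AbundanceSample(rng.multinomial(spec.depth_a, p_a))
    b = AbundanceSample(rng.multinomial(spec.depth_b, base))
    truth = {
        "composition": base,
        "composition_a": p_a,
        "effect_node": spec.effect_node if spec.effect_size > 0 else None,
        "effect_size": spec.effect_size,
    }
    return a, b, truth
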