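"""Permutation significance test for Haar-components.

Under the null that two samples come from compositionally identical
environments, the pooled reads are exchangeable, so the null distribution
of each component statistic ``lambda_v Delta_v^2`` can be estimated by
repeatedly re-drawing sample ``a`` from the pooled counts ``a + b``
without replacement — a multivariate hypergeometric draw with parameters
``(|a|; a + b)`` — and reassigning the remainder to ``b``.  One resample
stream serves every component at once: each resample costs a single O(n)
cumulative-sum pass, so testing all splits is no more expensive than
testing one.

The resample count follows the Dvoretzky–Kiefer–Wolfowitz inequality:
``N = ceil(log(2/delta) / (2 eps^2))`` resamples estimate each null c.d.f.
within sup-norm ``eps`` with probability ``1 - delta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diversity import AbundanceSample, haar_coordinates
from .haar import transform
from .tree import UNPLANTED, PlantedTree

__all__ = [
    "TestConfig",
    "dkw_sample_size",
    "mv_hypergeometric_sample",
    "permutation_pvalues",
    "adjust_pvalues",
]


def dkw_sample_size(epsilon: float, delta: float) -> int:
    """Resamples needed for a sup-norm-``epsilon`` c.d.f. estimate with
    failure probability ``delta``: ``ceil(ln(2/delta) / (2 epsilon^2))``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    return math.ceil(math.log(2.0 / delta) / (2.0 * epsilon * epsilon))


def mv_hypergeometric_sample(
    pool: np.ndarray, draw: int, rng: np.random.Generator, size: int | None = None
):
    """Exact multivariate hypergeometric draw(s) of ``draw`` items from
    ``pool``, with the complement returned alongside.

    Categories with zero pool receive zero.  Sampling is delegated to
    numpy's sequential conditional (marginals) method, which realizes the
    distribution exactly.
    """
    pool = np.asarray(pool, dtype=np.int64)
    if np.any(pool < 0):
        raise ValueError("pool counts must be nonnegative")
    total = int(pool.sum())
    if not 0 <= draw <= total:
        raise ValueError(f"draw={draw} out of range [0, {total}]")
    sample = rng.multivariate_hypergeometric(pool, draw, size=size, method="marginals")
    return sample, pool - sample


@dataclass
class TestConfig:
    """Parameters of the permutation test.

    ``N`` overrides the DKW-derived resample count when set.  ``comparison``
    selects the p-value estimator: ``"add_one"`` (default) reports
    ``(1 + #{resampled >= observed}) / (N + 1)``, which can never return 0
    and guards the tied-at-zero pathology; ``"strict"`` reports
    ``#{resampled > observed} / N`` with a ``1/N`` floor and a flag when no
    exceedance was seen (the discovery-probability style of reporting).
    """

    epsilon: float = 1e-4
    delta: float = 0.01
    N: int | None = None
    alpha: float = 0.05
    correction: str = "benjamini_hochberg"  # none | bonferroni | benjamini_hochberg
    bonferroni_m: int | None = None
    seed: int | None = None
    comparison: str = "add_one"  # add_one | strict
    chunk_size: int = 20_000
    max_work: float = 2e10  # resamples x leaves budget before refusing

    def __post_init__(self):
        if self.epsilon <= 0 or not 0 < self.delta < 1:
            raise ValueError("need epsilon > 0 and 0 < delta < 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.N is not None and self.N < 1:
            raise ValueError("N must be >= 1")
        if self.correction not in ("none", "bonferroni", "benjamini_hochberg"):
            raise ValueError(f"unknown correction: {self.correction!r}")
        if self.comparison not in ("add_one", "strict"):
            raise ValueError(f"unknown comparison: {self.comparison!r}")

    @property
    def resamples(self) -> int:
        return self.N if self.N is not None else dkw_sample_size(self.epsilon, self.delta)


def adjust_pvalues(p, method: str, m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m p), with ``m``
    defaulting to the vector length) or ``benjamini_hochberg`` step-up."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        m = len(p) if m is None else int(m)
        return np.minimum(1.0, m * p)
    if method == "benjamini_hochberg":
        if len(p) == 0:
            return p.copy()
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method: {method!r}")


def _null_exceedances(
    pool: np.ndarray,
    na: int,
    nb: int,
    basis,
    lambdas: np.ndarray,
    observed: np.ndarray,
    N: int,
    rng: np.random.Generator,
    chunk_size: int,
):
    """Stream N pooled-null resamples; count per-component exceedances.

    Returns (#{stat > obs}, #{stat >= obs}) without ever storing the
    resample matrix.
    """
    gt = np.zeros(len(observed), dtype=np.int64)
    ge = np.zeros(len(observed), dtype=np.int64)
    done = 0
    while done < N:
        m = min(chunk_size, N - done)
        a_new, _ = mv_hypergeometric_sample(pool, na, rng, size=m)
        f = a_new / na - (pool - a_new) / nb
        stats = lambdas * haar_coordinates(basis, f) ** 2
        gt += (stats > observed).sum(axis=0)
        ge += (stats >= observed).sum(axis=0)
        done += m
    return gt, ge


def permutation_pvalues(
    tree: PlantedTree,
    a: AbundanceSample,
    b: AbundanceSample,
    cfg: TestConfig | None = None,
    nodes=None,
    *,
    basis=None,
    lambdas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Empirical p-values for the Haar-components of ``d_h(a, b)``.

    Pools the two count vectors, streams ``cfg.resamples`` multivariate
    hypergeometric re-splits, and recomputes every component statistic per
    resample from one cumulative-sum pass.  ``nodes`` restricts the report
    to a subset of tree node ids (all splits are still computed — they ride
    the same resample stream for free).  ``basis``/``lambdas`` may be
    passed to amortize the transform across repeated calls.

    Returns a DataFrame sorted by observed component magnitude with
    columns: wavelet, node, depth, n_leaves, component, exceedances,
    p_raw, p_adjusted, floor_flag.
    """
    cfg = cfg or TestConfig()
    if a.total == 0 or b.total == 0:
        raise ValueError("samples must have positive total counts")
    if basis is None or lambdas is None:
        st = transform(tree)
        basis, lambdas = st.basis, st.diagonal
    N = cfg.resamples
    if N * basis.n_leaves > cfg.max_work:
        raise ValueError(
            f"N * n_leaves = {N * basis.n_leaves:.3g} exceeds max_work={cfg.max_work:.3g}; "
            "raise epsilon, set cfg.N, or raise cfg.max_work (resamples are streamed, "
            "so the limit is time, not memory)"
        )

    pool = np.asarray(a.counts, dtype=np.int64) + np.asarray(b.counts, dtype=np.int64)
    f = a.relative() - b.relative()
    delta = haar_coordinates(basis, f)
    observed = lambdas * delta**2

    rng = np.random.default_rng(cfg.seed)
    gt, ge = _null_exceedances(
        pool, a.total, b.total, basis, lambdas, observed, N, rng, cfg.chunk_size
    )

    if cfg.comparison == "strict":
        exceed = gt
        p_raw = gt / N
        floor = exceed == 0
        p_raw = np.where(floor, 1.0 / N, p_raw)
    else:
        exceed = ge
        p_raw = (1.0 + ge) / (N + 1.0)
        floor = np.zeros(len(ge), dtype=bool)

    p_adj = adjust_pvalues(p_raw, cfg.correction, m=cfg.bonferroni_m)

    t = basis.tree
    depth = t.depths(UNPLANTED)
    lo, hi = t._intervals()
    df = pd.DataFrame(
        {
            "wavelet": np.arange(basis.n_wavelets),
            "node": basis.nodes,
            "depth": depth[basis.nodes],
            "n_leaves": (hi - lo)[basis.nodes],
            "component": observed,
            "delta": delta,
            "exceedances": exceed,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "floor_flag": floor,
        }
    )
    if nodes is not None:
        df = df[df["node"].isin(list(nodes))]
    order = np.lexsort((df["wavelet"].to_numpy(), -df["component"].to_numpy()))
    return df.iloc[order].reset_index(drop=True)
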