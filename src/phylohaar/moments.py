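"""Exact recursions and asymptotic expansions for leaf-depth and
external-path-length moments of critical beta-splitting trees.

Let ``L_n`` be the edge-depth of a uniformly random leaf of a critical
beta-splitting tree with ``n`` leaves (unplanted convention, ``L_1 = 0``).
Conditioning on the top split of size ``(i, n - i)`` and on which side the
leaf falls gives the exact recursions (``h_k`` the harmonic numbers)

    E(L_n)   = 1 + (1/h_{n-1}) sum_i E(L_i) / (n - i),
    E(L_n^2) = 1 + (1/h_{n-1}) sum_i [2 E(L_i) + E(L_i^2)] / (n - i),

and for the product ``Z_n = L_{n,1} L_{n,2}`` of the depths of two distinct
random leaves

    E(Z_n) = 2 E(L_n) - 1
             + (1/((n-1) h_{n-1})) sum_i (i-1)/(n-i) E(Z_i)
             + (1/((n-1) h_{n-1})) sum_i E(L_i) E(L_{n-i}).

Exchangeability of the leaf depths then yields the EPL moments:
``E(EPL) = n E(L_n)`` and ``E(EPL^2) = n E(L_n^2) + n(n-1) E(Z_n)``.

The matching asymptotic expansions are polynomials in ``log n`` whose
coefficients involve the Riemann zeta values ``zeta_2..zeta_4`` and
Euler's constant; the leading terms of ``E(EPL^2)`` and ``E(EPL)^2``
coincide and cancel in the variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import mpmath as mp
import numpy as np
import pandas as pd

from .ensembles import CRITICAL_BETA, EnsembleConfig, sample_tree
from .tree import UNPLANTED, external_path_length

__all__ = [
    "MomentTable",
    "AsymptoticConstants",
    "constants",
    "depth_moments_exact",
    "pair_product_exact",
    "epl_moments_exact",
    "epl_mean_asymptotic",
    "epl_second_moment_asymptotic",
    "epl_variance_asymptotic",
    "depth_mean_asymptotic",
    "depth_variance_asymptotic",
    "epl_expansion_coefficients",
    "monte_carlo_epl",
]

#: size cap below which the recursions run in exact rational arithmetic
RATIONAL_CAP = 128


def _resolve_arithmetic(N: int, arithmetic: str) -> str:
    if arithmetic == "auto":
        return "rational" if N <= RATIONAL_CAP else "float"
    if arithmetic not in ("rational", "float"):
        raise ValueError(f"unknown arithmetic: {arithmetic!r}")
    return arithmetic


def depth_moments_exact(N: int, arithmetic: str = "auto"):
    """First two moments of ``L_n`` for ``n = 1..N`` (index 0 unused).

    Rational mode returns lists of :class:`fractions.Fraction` (exact);
    float mode returns float64 arrays — the recursions are sums of
    positive, well-scaled terms, so double precision carries ~1e-12
    relative error.  O(N^2) either way.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    mode = _resolve_arithmetic(N, arithmetic)
    if mode == "rational":
        EL: list = [None, Fraction(0)]
        EL2: list = [None, Fraction(0)]
        h = Fraction(0)
        for n in range(2, N + 1):
            h += Fraction(1, n - 1)  # h_{n-1}
            s1 = sum(EL[i] / (n - i) for i in range(1, n))
            s2 = sum((2 * EL[i] + EL2[i]) / (n - i) for i in range(1, n))
            EL.append(1 + s1 / h)
            EL2.append(1 + s2 / h)
        return EL, EL2
    EL = np.zeros(N + 1)
    EL2 = np.zeros(N + 1)
    inv = np.zeros(N + 1)
    inv[1:] = 1.0 / np.arange(1, N + 1)
    h = np.cumsum(inv)  # h[k] = h_k
    for n in range(2, N + 1):
        w = inv[n - 1 : 0 : -1]  # 1/(n-i), i = 1..n-1
        EL[n] = 1.0 + (EL[1:n] @ w) / h[n - 1]
        EL2[n] = 1.0 + ((2.0 * EL[1:n] + EL2[1:n]) @ w) / h[n - 1]
    return EL, EL2


def pair_product_exact(N: int, EL=None, arithmetic: str = "auto"):
    """``E(Z_n) = E(L_{n,1} L_{n,2})`` for ``n = 2..N`` (indices 0, 1 unused)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    mode = _resolve_arithmetic(N, arithmetic)
    if EL is None:
        EL = depth_moments_exact(N, mode)[0]
    if mode == "rational":
        EZ: list = [None, Fraction(0)]
        h = Fraction(0)
        for n in range(2, N + 1):
            h += Fraction(1, n - 1)
            anc = sum(Fraction(i - 1, n - i) * EZ[i] for i in range(2, n))
            conv = sum(EL[i] * EL[n - i] for i in range(1, n))
            EZ.append(2 * EL[n] - 1 + (anc + conv) / ((n - 1) * h))
        return EZ
    EL = np.asarray(EL, dtype=np.float64)
    EZ = np.zeros(N + 1)
    inv = np.zeros(N + 1)
    inv[1:] = 1.0 / np.arange(1, N + 1)
    h = np.cumsum(inv)
    idx = np.arange(N + 1, dtype=np.float64)
    for n in range(2, N + 1):
        w = (idx[1:n] - 1.0) * inv[n - 1 : 0 : -1]  # (i-1)/(n-i)
        conv = EL[1:n] @ EL[n - 1 : 0 : -1]
        EZ[n] = 2.0 * EL[n] - 1.0 + (EZ[1:n] @ w + conv) / ((n - 1) * h[n - 1])
    return EZ


@dataclass
class MomentTable:
    """Exact depth and EPL moments for ``n = 1..N`` (unplanted convention).

    Arrays are indexed by ``n`` directly (entry 0 unused); rational mode
    stores Fractions in object arrays.
    """

    N: int
    EL: np.ndarray
    EL2: np.ndarray
    EZ: np.ndarray
    EPL1: np.ndarray
    EPL2: np.ndarray
    VarEPL: np.ndarray
    arithmetic: str

    def to_frame(self) -> pd.DataFrame:
        n = np.arange(1, self.N + 1)
        return pd.DataFrame(
            {
                "n": n,
                "EL": [self.EL[k] for k in n],
                "EL2": [self.EL2[k] for k in n],
                "EZ": [self.EZ[k] for k in n],
                "EPL1": [self.EPL1[k] for k in n],
                "EPL2": [self.EPL2[k] for k in n],
                "VarEPL": [self.VarEPL[k] for k in n],
            }
        )


def epl_moments_exact(N: int, arithmetic: str = "auto") -> MomentTable:
    """Exact EPL moment table from the depth recursions.

    ``E(EPL) = n E(L_n)``; ``E(EPL^2) = n E(L_n^2) + n(n-1) E(Z_n)`` by
    exchangeability of the relabelled leaf depths.
    """
    mode = _resolve_arithmetic(N, arithmetic)
    EL, EL2 = depth_moments_exact(N, mode)
    if N >= 2:
        EZ = pair_product_exact(N, EL, mode)
    else:
        EZ = [None, Fraction(0)] if mode == "rational" else np.zeros(2)
    if mode == "rational":
        pad = lambda lst: np.array([Fraction(0)] + list(lst[1:]) + [Fraction(0)] * (N + 1 - len(lst)), dtype=object)
        ELa, EL2a, EZa = pad(EL), pad(EL2), pad(EZ)
        n = np.array([Fraction(k) for k in range(N + 1)], dtype=object)
    else:
        ELa, EL2a, EZa = np.asarray(EL), np.asarray(EL2), np.asarray(EZ)
        if len(EZa) < N + 1:
            EZa = np.concatenate([EZa, np.zeros(N + 1 - len(EZa))])
        n = np.arange(N + 1, dtype=np.float64)
    EPL1 = n * ELa
    EPL2 = n * EL2a + n * (n - 1) * EZa
    return MomentTable(N, ELa, EL2a, EZa, EPL1, EPL2, EPL2 - EPL1**2, mode)


# ---------------------------------------------------------------------- #
# asymptotics
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class AsymptoticConstants:
    """High-precision constants of the moment expansions.

    ``b0`` refines the O(1) term of ``E(L_n)``; ``C2, C1`` are the
    ``n^2 log^2`` and ``n^2 log`` coefficients of ``E(EPL^2)``; ``B1`` the
    ``n^2 log`` coefficient of ``Var(EPL)``.
    """

    zeta2: mp.mpf
    zeta3: mp.mpf
    zeta4: mp.mpf
    gamma: mp.mpf
    b0: mp.mpf
    C2: mp.mpf
    C1: mp.mpf
    B1: mp.mpf


@lru_cache(maxsize=None)
def constants(dps: int = 50) -> AsymptoticConstants:
    with mp.workdps(dps):
        z2, z3, z4 = mp.zeta(2), mp.zeta(3), mp.zeta(4)
        g = mp.euler
        b0 = g**2 / (2 * z2) + g * z3 / z2**2 + z3**2 / z2**3 + mp.mpf(1) / 10
        C2 = (
            -mp.mpf(9) / (10 * z2)
            + (3 * g**2 + 4 * z3) / (2 * z2**2)
            + 3 * g * z3 / z2**3
            + 2 * z3**2 / z2**4
        )
        C1 = (
            1
            - (9 * g + 20 * z3) / (5 * z2)
            + (5 * g**3 + 20 * z3 * g + 21 * z3 - 30 * z4) / (5 * z2**2)
            + (3 * z3 * g**2 + 4 * z3**2) / z2**3
            + 4 * z3**2 * g / z2**4
            + 2 * z3**3 / z2**5
        )
        B1 = (
            1
            - (2 * g + 4 * z3) / z2
            + (4 * z3 * g + 4 * z3 - 6 * z4) / z2**2
            + 4 * z3**2 / z2**3
        )
        return AsymptoticConstants(z2, z3, z4, g, b0, C2, C1, B1)


def epl_expansion_coefficients() -> dict:
    """Expansion coefficients keyed by (power of n, power of log n).

    Returns dicts for the EPL mean, the EPL second moment, the square of
    the mean expansion, and the variance, enabling symbolic-level checks
    (e.g. the cancellation of the ``n^2 log^4`` and ``n^2 log^3`` terms
    in the variance).
    """
    c = constants()
    a1 = 1 / (2 * c.zeta2)
    a2 = (c.gamma * c.zeta2 + c.zeta3) / c.zeta2**2
    mean = {(1, 2): a1, (1, 1): a2, (1, 0): c.b0}
    second = {(2, 4): 1 / (4 * c.zeta2**2), (2, 3): a2 / c.zeta2, (2, 2): c.C2, (2, 1): c.C1}
    mean_sq = {
        (2, 4): a1 * a1,
        (2, 3): 2 * a1 * a2,
        (2, 2): a2 * a2 + 2 * a1 * c.b0,
        (2, 1): 2 * a2 * c.b0,
        (2, 0): c.b0 * c.b0,
    }
    var = {(2, 2): 2 * c.zeta3 / c.zeta2**2 - 1 / c.zeta2, (2, 1): c.B1}
    return {"mean": mean, "second": second, "mean_squared": mean_sq, "var": var}


def _evaluate(coeffs: dict, n: int) -> float:
    ln = mp.log(n)
    return float(sum(c * mp.mpf(n) ** pn * ln**pl for (pn, pl), c in coeffs.items()))


def epl_mean_asymptotic(n: int) -> float:
    """E(EPL): ``n log^2 n / (2 zeta2) + (gamma zeta2 + zeta3)/zeta2^2 n log n
    + b0 n`` (error O(log n))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return _evaluate(epl_expansion_coefficients()["mean"], n)


def epl_second_moment_asymptotic(n: int) -> float:
    """E(EPL^2) polynomial through the ``n^2 log n`` term (error O(n^2))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return _evaluate(epl_expansion_coefficients()["second"], n)


def epl_variance_asymptotic(n: int) -> float:
    """Var(EPL) = (2 zeta3/zeta2^2 - 1/zeta2) n^2 log^2 n + B1 n^2 log n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return _evaluate(epl_expansion_coefficients()["var"], n)


def depth_mean_asymptotic(n: int, refined: bool = True) -> float:
    """E(L_n) expansion; ``refined`` includes the constant term ``b0``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    c = constants()
    ln = mp.log(n)
    val = ln**2 / (2 * c.zeta2) + (c.gamma * c.zeta2 + c.zeta3) / c.zeta2**2 * ln
    if refined:
        val += c.b0
    return float(val)


def depth_variance_asymptotic(n: int) -> float:
    """Var(L_n) = 2 zeta3 / (3 zeta2^3) log^3 n + O(log^2 n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    c = constants()
    return float(2 * c.zeta3 / (3 * c.zeta2**3) * mp.log(n) ** 3)


# ---------------------------------------------------------------------- #
# Monte Carlo
# ---------------------------------------------------------------------- #


def monte_carlo_epl(
    law: str = CRITICAL_BETA,
    n: int = 100,
    reps: int = 200,
    seed: int | None = None,
    convention: str = UNPLANTED,
) -> dict:
    """Sample mean/variance of EPL over ``reps`` simulated trees, with
    standard errors (variance SE via the usual normal-theory approximation)."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for k in range(reps):
        t = sample_tree(EnsembleConfig(n=n, law=law), rng=rng)
        vals[k] = external_path_length(t, convention)
    mean = float(vals.mean())
    var = float(vals.var(ddof=1))
    return {
        "n": n,
        "reps": reps,
        "mean": mean,
        "mean_se": float(np.sqrt(var / reps)),
        "var": var,
        "var_se": float(var * np.sqrt(2.0 / (reps - 1))),
    }
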