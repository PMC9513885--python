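"""Exact null distribution of the overlap statistic via generating polynomials.

For a weight vector **w** the generating polynomial is ``prod_w (1 + x^w y)``:
the coefficient of ``x^v y^k`` counts the k-subsets of weights summing to v.
Restricting to a fixed power of ``y`` therefore yields the distribution of
the statistic addend over uniformly random terms of that cardinality, and the
product of the miRNA and mRNA restrictions is the exact null distribution of
the full statistic.  All coefficients are arbitrary-precision integers and
the p-value is an exact rational; no floating point is involved.

Two construction routes are provided.  :func:`restricted_genpoly` is the
production path: equal weights are grouped and expanded binomially, groups
are convolved by dynamic programming with the y-dimension truncated at the
term cardinality and the x-dimension capped at the largest attainable sum.
:func:`naive_restricted_genpoly` multiplies the factors term by term and
exists as an independent cross-check for the test suite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Dict, Iterable

import numpy as np

from .graph import CircNeighborhood

__all__ = [
    "RestrictedPolynomial",
    "NullDistribution",
    "restricted_genpoly",
    "naive_restricted_genpoly",
    "null_distribution",
    "exact_pvalue",
    "null_mean",
]


@dataclass(frozen=True)
class RestrictedPolynomial:
    """Coefficients of the generating polynomial at a fixed power of y.

    ``coeffs[v]`` is the number of ``k``-subsets of the weight vector whose
    entries sum to ``v``; the coefficients sum to ``C(n, k)``.
    """

    k: int
    coeffs: Dict[int, int]

    def total(self) -> int:
        return sum(self.coeffs.values())


@dataclass(frozen=True)
class NullDistribution:
    """Exact counts of the statistic over all subset pairs of fixed sizes."""

    counts: Dict[int, int]
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("null distribution has no mass")
        if sum(self.counts.values()) != self.total:
            raise ValueError("null counts do not sum to the combination total")


def _as_weights(weights: Iterable[int]) -> np.ndarray:
    w = np.asarray(list(weights) if not isinstance(weights, np.ndarray) else weights)
    w = w.astype(np.int64)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return w


def restricted_genpoly(weights: Iterable[int], k: int) -> RestrictedPolynomial:
    """Coefficients of ``prod_w (1 + x^w y)`` restricted to ``y^k``.

    Weights sharing a value collapse into one factor ``(1 + x^w y)^n`` whose
    restriction is known in closed form via the binomial theorem, so the
    dynamic program convolves one table per *distinct* weight rather than
    one per RNA.  Zero weights contribute ``(1 + y)^{n0}`` and are folded in
    analytically at the end; intermediate x-powers above the sum of the
    ``k`` largest weights are dropped, as no completion can bring them back
    under the cap.
    """
    w = _as_weights(weights)
    n = w.size
    if not (0 <= k <= n):
        raise ValueError(f"k={k} out of range [0, {n}]")
    if k == 0:
        return RestrictedPolynomial(k=0, coeffs={0: 1})

    groups = Counter(int(v) for v in w)
    n_zero = groups.pop(0, 0)
    # cap: best attainable sum using k entries
    cap = int(np.sort(w)[::-1][:k].sum())

    # dp[j] maps x-power -> count over subsets of size j from processed groups
    dp: list[Dict[int, int]] = [{0: 1}] + [dict() for _ in range(k)]
    for wt, cnt in sorted(groups.items()):
        new: list[Dict[int, int]] = [dict() for _ in range(k + 1)]
        for j in range(k + 1):
            for t in range(0, min(cnt, j) + 1):
                c = comb(cnt, t)
                add = wt * t
                for v, m in dp[j - t].items():
                    nv = v + add
                    if nv > cap:
                        continue
                    new[j][nv] = new[j].get(nv, 0) + c * m
        dp = new

    # fold the zero-weight group (1 + y)^{n_zero}: it moves mass across j
    # at x-power 0 only
    coeffs: Dict[int, int] = {}
    for j in range(max(0, k - n_zero), k + 1):
        c = comb(n_zero, k - j)
        if c == 0:
            continue
        for v, m in dp[j].items():
            coeffs[v] = coeffs.get(v, 0) + c * m
    return RestrictedPolynomial(k=k, coeffs=coeffs)


def naive_restricted_genpoly(weights: Iterable[int], k: int) -> RestrictedPolynomial:
    """Term-by-term product of the factors ``(1 + x^w y)``, then restriction.

    Exponential-size intermediate in the worst case; used only as an
    independent oracle in tests.
    """
    w = _as_weights(weights)
    if not (0 <= k <= w.size):
        raise ValueError(f"k={k} out of range [0, {w.size}]")
    # poly maps (x-power, y-power) -> coefficient
    poly: Dict[tuple, int] = {(0, 0): 1}
    for wt in w:
        new: Dict[tuple, int] = {}
        for (v, j), m in poly.items():
            new[(v, j)] = new.get((v, j), 0) + m
            key = (v + int(wt), j + 1)
            new[key] = new.get(key, 0) + m
        poly = new
    coeffs = {v: m for (v, j), m in poly.items() if j == k}
    return RestrictedPolynomial(k=k, coeffs=coeffs)


def null_distribution(nb: CircNeighborhood, k_mu: int, k_m: int) -> NullDistribution:
    """Exact null distribution of the statistic for term sizes (k_mu, k_m).

    The null draws ``k_mu`` miRNAs and ``k_m`` mRNAs uniformly and
    independently from the *full* universes; the distribution is the
    convolution over x of the two restricted polynomials, with total mass
    ``C(|mu|, k_mu) * C(|m|, k_m)``.
    """
    p_mu = restricted_genpoly(nb.mirna_weights, k_mu)
    p_m = restricted_genpoly(nb.mrna_weights, k_m)
    counts: Dict[int, int] = {}
    for v1, m1 in p_mu.coeffs.items():
        for v2, m2 in p_m.coeffs.items():
            counts[v1 + v2] = counts.get(v1 + v2, 0) + m1 * m2
    total = comb(nb.mirna_weights.size, k_mu) * comb(nb.mrna_weights.size, k_m)
    return NullDistribution(counts=counts, total=total)


def exact_pvalue(null: NullDistribution, s_obs: int) -> Fraction:
    """Upper-tail probability ``P(S >= s_obs)`` under the exact null.

    The comparison is inclusive: the observed configuration itself counts
    toward the tail, so any attainable observation gives ``p >= 1/total``
    and ``s_obs = 0`` gives exactly 1.
    """
    if s_obs < 0:
        raise ValueError("observed statistic must be non-negative")
    tail = sum(m for v, m in null.counts.items() if v >= s_obs)
    return Fraction(tail, null.total)


def null_mean(null: NullDistribution) -> Fraction:
    """Exact mean of the null distribution."""
    return Fraction(
        sum(v * m for v, m in null.counts.items()), null.total
    )
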