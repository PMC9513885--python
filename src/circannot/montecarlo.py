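"""Monte-Carlo reference estimator for the annotation p-value.

Draws random annotation terms of the observed cardinalities and counts how
often the resampled statistic reaches the observed one.  Serves as the
stochastic baseline the exact generating-polynomial engine is validated
against; the estimate uses the positively biased form (r+1)/(n+1), which
never reports an impossible zero p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .graph import CircNeighborhood

__all__ = ["MonteCarloEstimate", "sample_pvalue"]


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Outcome of n resampling trials against an observed statistic."""

    r: int
    n: int
    seed: int

    @property
    def p_hat(self) -> Fraction:
        return Fraction(self.r + 1, self.n + 1)


def sample_pvalue(
    nb: CircNeighborhood,
    k_mu: int,
    k_m: int,
    s_obs: int,
    n: int,
    seed: int,
) -> MonteCarloEstimate:
    """Estimate ``P(S >= s_obs)`` by resampling random terms.

    Each trial draws ``k_mu`` miRNAs and ``k_m`` mRNAs uniformly without
    replacement and independently of each other, matching the product-form
    null of the exact engine.  Randomness comes from one
    ``numpy.random.Generator`` seeded per call; no global state.
    """
    if n < 1:
        raise ValueError("number of trials must be at least 1")
    n_mu = nb.mirna_weights.size
    n_m = nb.mrna_weights.size
    if not (0 <= k_mu <= n_mu):
        raise ValueError(f"k_mu={k_mu} out of range [0, {n_mu}]")
    if not (0 <= k_m <= n_m):
        raise ValueError(f"k_m={k_m} out of range [0, {n_m}]")
    rng = np.random.default_rng(seed)

    def subset_sums(weights: np.ndarray, k: int) -> np.ndarray:
        if k == 0:
            return np.zeros(n, dtype=np.int64)
        # rank a uniform matrix per row: argpartition gives a uniform
        # k-subset per trial without a Python-level loop
        keys = rng.random((n, weights.size))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        return weights[idx].sum(axis=1)

    s = subset_sums(nb.mirna_weights, k_mu) + subset_sums(nb.mrna_weights, k_m)
    r = int((s >= s_obs).sum())
    return MonteCarloEstimate(r=r, n=n, seed=seed)
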