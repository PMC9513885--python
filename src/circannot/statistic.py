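"""Path-count overlap statistic and its decomposition.

The overlap statistic ``s(c, g)`` counts the directed paths from a circRNA
*c* that terminate in an RNA annotated with term *g*: length-1 paths ending
in annotated miRNAs plus length-2 paths ending in annotated mRNAs.  All
arithmetic here is exact (Python integers and :class:`fractions.Fraction`);
floating point enters only when reports are written.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .graph import CircNeighborhood

__all__ = [
    "AnnotationTerm",
    "InfluenceReport",
    "statistic",
    "expected_statistic",
    "normalized_statistic",
    "influence",
]


@dataclass(frozen=True)
class AnnotationTerm:
    """Binary membership of one annotation term over both RNA universes."""

    term_id: str
    g_mu: np.ndarray
    g_m: np.ndarray
    description: str = ""

    def __post_init__(self):
        gmu = np.asarray(self.g_mu, dtype=np.int64)
        gm = np.asarray(self.g_m, dtype=np.int64)
        for name, arr in (("g_mu", gmu), ("g_m", gm)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        object.__setattr__(self, "g_mu", gmu)
        object.__setattr__(self, "g_m", gm)

    @property
    def k_mu(self) -> int:
        """Number of member miRNAs present in the graph universe."""
        return int(self.g_mu.sum())

    @property
    def k_m(self) -> int:
        """Number of member mRNAs present in the graph universe."""
        return int(self.g_m.sum())

    @property
    def size(self) -> int:
        return self.k_mu + self.k_m


@dataclass(frozen=True)
class InfluenceReport:
    """Per-RNA drop of the statistic when the RNA is deleted from the graph."""

    delta_mu: np.ndarray
    delta_m: np.ndarray
    mirna_ids: tuple
    mrna_ids: tuple


def _check_dims(nb: CircNeighborhood, term: AnnotationTerm) -> None:
    if term.g_mu.shape != nb.mirna_weights.shape:
        raise ValueError(
            f"miRNA dimension mismatch: term has {term.g_mu.size}, "
            f"neighborhood has {nb.mirna_weights.size}"
        )
    if term.g_m.shape != nb.mrna_weights.shape:
        raise ValueError(
            f"mRNA dimension mismatch: term has {term.g_m.size}, "
            f"neighborhood has {nb.mrna_weights.size}"
        )


def statistic(nb: CircNeighborhood, term: AnnotationTerm) -> int:
    """Number of directed paths from the circRNA ending in a term member."""
    _check_dims(nb, term)
    return int(nb.mirna_weights @ term.g_mu + nb.mrna_weights @ term.g_m)


def expected_statistic(nb: CircNeighborhood, k_mu: int, k_m: int) -> Fraction:
    """Mean of the statistic over uniformly random terms of fixed sizes.

    A random term with ``k_mu`` miRNAs drawn uniformly from the universe
    annotates each miRNA with probability ``k_mu/|mu|``; by linearity the
    expected miRNA addend is that fraction of the total miRNA weight, and
    analogously for mRNAs.  Returned exactly; equals the mean of the exact
    null distribution.
    """
    n_mu = nb.mirna_weights.size
    n_m = nb.mrna_weights.size
    if not (0 <= k_mu <= n_mu):
        raise ValueError(f"k_mu={k_mu} out of range [0, {n_mu}]")
    if not (0 <= k_m <= n_m):
        raise ValueError(f"k_m={k_m} out of range [0, {n_m}]")
    return Fraction(k_mu, n_mu) * int(nb.mirna_weights.sum()) + Fraction(
        k_m, n_m
    ) * int(nb.mrna_weights.sum())


def normalized_statistic(s: int, expected: Fraction) -> Fraction:
    """Ratio ``s / E[s]``; values above 1 indicate over-representation.

    Raises
    ------
    ZeroDivisionError
        If the expectation is zero (the ratio is undefined; report the
        value as missing, not as infinity).
    """
    if expected == 0:
        raise ZeroDivisionError("normalized statistic undefined for E[s] = 0")
    return Fraction(s) / Fraction(expected)


def influence(
    nb: CircNeighborhood, term: AnnotationTerm, mirna_mrna: np.ndarray
) -> InfluenceReport:
    """Split the statistic among the individual RNAs.

    ``delta_mu[i]`` is the drop in ``s`` when miRNA *i* and all its
    incident edges are removed: its own membership hit plus every length-2
    path it mediates to an annotated mRNA.  ``delta_m[j]`` is the drop when
    mRNA *j* is removed, i.e. its path count if annotated, else 0.  The
    miRNA deltas sum to the full statistic.
    """
    _check_dims(nb, term)
    mm = np.asarray(mirna_mrna, dtype=np.int64)
    if mm.shape != (nb.mrna_weights.size, nb.mirna_weights.size):
        raise ValueError(
            f"mirna_mrna shape {mm.shape} does not match "
            f"({nb.mrna_weights.size}, {nb.mirna_weights.size})"
        )
    delta_mu = nb.mirna_weights * (term.g_mu + mm.T @ term.g_m)
    delta_m = nb.mrna_weights * term.g_m
    return InfluenceReport(
        delta_mu=delta_mu,
        delta_m=delta_m,
        mirna_ids=nb.mirna_ids,
        mrna_ids=nb.mrna_ids,
    )
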