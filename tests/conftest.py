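"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the production code paths: path counts
come from explicit path enumeration on the graph, and null distributions
from exhaustive iteration over every subset pair of the two universes.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction
from typing import Tuple

import numpy as np
import pytest

from circannot import (
    AnnotationTerm,
    CircNeighborhood,
    InteractionGraph,
    example_network,
    neighborhood,
)


@pytest.fixture
def example() -> Tuple[InteractionGraph, AnnotationTerm, CircNeighborhood]:
    graph, term = example_network()
    return graph, term, neighborhood(graph, "circ-1")


def enumerate_path_counts(circ_row: np.ndarray, mirna_mrna: np.ndarray) -> np.ndarray:
    """Count circRNA->miRNA->mRNA paths per mRNA by explicit enumeration."""
    n_m, n_mu = mirna_mrna.shape
    counts = np.zeros(n_m, dtype=np.int64)
    for j in range(n_m):
        for i in range(n_mu):
            if circ_row[i] == 1 and mirna_mrna[j, i] == 1:
                counts[j] += 1
    return counts


def exhaustive_null(
    mirna_weights: np.ndarray, mrna_weights: np.ndarray, k_mu: int, k_m: int
) -> Counter:
    """Statistic multiplicities over every (miRNA-subset, mRNA-subset) pair."""
    counts: Counter = Counter()
    mu_idx = range(len(mirna_weights))
    m_idx = range(len(mrna_weights))
    for mu_sub in itertools.combinations(mu_idx, k_mu):
        s_mu = sum(int(mirna_weights[i]) for i in mu_sub)
        for m_sub in itertools.combinations(m_idx, k_m):
            s = s_mu + sum(int(mrna_weights[j]) for j in m_sub)
            counts[s] += 1
    return counts


def exhaustive_pvalue(counts: Counter, s_obs: int) -> Fraction:
    total = sum(counts.values())
    return Fraction(sum(m for v, m in counts.items() if v >= s_obs), total)


def random_small_instance(seed: int, max_mu: int = 6, max_m: int = 8):
    """A random neighborhood + term cardinalities small enough to enumerate."""
    rng = np.random.default_rng(seed)
    n_mu = int(rng.integers(1, max_mu + 1))
    n_m = int(rng.integers(1, max_m + 1))
    a = rng.integers(0, 2, size=n_mu)
    A = rng.integers(0, 2, size=(n_m, n_mu))
    nb = CircNeighborhood(
        circ_id="c",
        mirna_weights=a,
        mrna_weights=A @ a,
        mirna_ids=tuple(f"mu{i}" for i in range(n_mu)),
        mrna_ids=tuple(f"m{j}" for j in range(n_m)),
    )
    k_mu = int(rng.integers(0, n_mu + 1))
    k_m = int(rng.integers(0, n_m + 1))
    return nb, A, k_mu, k_m


def random_term_for(nb: CircNeighborhood, k_mu: int, k_m: int, seed: int) -> AnnotationTerm:
    rng = np.random.default_rng(seed)
    g_mu = np.zeros(nb.mirna_weights.size, dtype=np.int64)
    g_m = np.zeros(nb.mrna_weights.size, dtype=np.int64)
    g_mu[rng.choice(g_mu.size, size=k_mu, replace=False)] = 1
    g_m[rng.choice(g_m.size, size=k_m, replace=False)] = 1
    return AnnotationTerm(term_id=f"T{seed}", g_mu=g_mu, g_m=g_m)
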