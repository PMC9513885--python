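"""Per-circRNA annotation over a battery of terms.

Filters terms by size, computes the exact p-value of each surviving term
against the circRNA's neighborhood, adjusts for multiple testing over the
surviving family, and returns a sorted result table.  Adjusted p-values are
computed in exact rational arithmetic so that the whole pipeline stays
bit-reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence

from .genpoly import exact_pvalue, null_distribution
from .graph import InteractionGraph, neighborhood
from .montecarlo import sample_pvalue
from .statistic import AnnotationTerm, expected_statistic, statistic

__all__ = [
    "AnnotationResult",
    "filter_terms",
    "adjust_pvalues",
    "annotate_circrna",
]

logger = logging.getLogger(__name__)

#: default size window for terms, inclusive at both ends; very small terms
#: are statistically fragile and very large ones uninformative
DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 1000


@dataclass(frozen=True)
class AnnotationResult:
    """One row of the annotation report for a (circRNA, term) pair."""

    term_id: str
    size: int
    s: int
    expected: Fraction
    ratio: Optional[Fraction]
    p: Fraction
    p_bonferroni: Fraction
    p_holm: Fraction
    p_fdr: Fraction
    elapsed: float = 0.0
    p_mc: Optional[Fraction] = None
    description: str = ""


def filter_terms(
    terms: Iterable[AnnotationTerm],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> List[AnnotationTerm]:
    """Keep terms whose in-graph member count lies in [min_size, max_size]."""
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    return [t for t in terms if min_size <= t.size <= max_size]


def adjust_pvalues(
    p: Sequence[Fraction], method: str = "bonferroni"
) -> List[Fraction]:
    """Multiple-testing adjustment in exact rational arithmetic.

    ``bonferroni`` multiplies by the family size; ``holm`` is the step-down
    family-wise procedure; ``bh`` is the Benjamini–Hochberg step-up FDR
    procedure.  All outputs are capped at 1 and returned in input order.
    """
    p = [Fraction(x) for x in p]
    m = len(p)
    if m == 0:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    one = Fraction(1)
    if method == "bonferroni":
        return [min(one, x * m) for x in p]
    order = sorted(range(m), key=lambda i: (p[i], i))
    adj = [Fraction(0)] * m
    if method == "holm":
        running = Fraction(0)
        for rank, i in enumerate(order):
            running = max(running, min(one, (m - rank) * p[i]))
            adj[i] = running
        return adj
    if method == "bh":
        running = one
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, min(one, Fraction(m, rank + 1) * p[i]))
            adj[i] = running
        return adj
    raise ValueError(f"unknown adjustment method: {method!r}")


def annotate_circrna(
    graph: InteractionGraph,
    circ_id: str,
    terms: Iterable[AnnotationTerm],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    mc_trials: Optional[int] = None,
    seed: Optional[int] = None,
) -> List[AnnotationResult]:
    """Annotate one circRNA against a term battery.

    Each surviving term gets the overlap statistic, its expectation, the
    normalized ratio, and the exact p-value from the generating-polynomial
    null.  With ``mc_trials`` set, a Monte-Carlo estimate is computed
    alongside for cross-validation.  Rows are sorted by ascending p-value
    (ties by term id); adjustments are computed over the surviving family
    only, so they are invariant to the input order of the terms.
    """
    nb = neighborhood(graph, circ_id)
    kept = filter_terms(terms, min_size=min_size, max_size=max_size)
    if not kept:
        logger.warning(
            "no terms within size window [%d, %d] for %s",
            min_size,
            max_size,
            circ_id,
        )
        return []

    raw: List[dict] = []
    for idx, term in enumerate(kept):
        t0 = time.perf_counter()
        s = statistic(nb, term)
        expected = expected_statistic(nb, term.k_mu, term.k_m)
        null = null_distribution(nb, term.k_mu, term.k_m)
        p = exact_pvalue(null, s)
        elapsed = time.perf_counter() - t0
        p_mc = None
        if mc_trials is not None:
            if seed is None:
                raise ValueError("mc_trials requires an explicit seed")
            p_mc = sample_pvalue(
                nb, term.k_mu, term.k_m, s, mc_trials, seed + idx
            ).p_hat
        raw.append(
            dict(
                term=term,
                s=s,
                expected=expected,
                ratio=Fraction(s) / expected if expected > 0 else None,
                p=p,
                p_mc=p_mc,
                elapsed=elapsed,
            )
        )

    ps = [r["p"] for r in raw]
    bonf = adjust_pvalues(ps, "bonferroni")
    holm = adjust_pvalues(ps, "holm")
    bh = adjust_pvalues(ps, "bh")
    results = [
        AnnotationResult(
            term_id=r["term"].term_id,
            size=r["term"].size,
            s=r["s"],
            expected=r["expected"],
            ratio=r["ratio"],
            p=r["p"],
            p_bonferroni=pb,
            p_holm=ph,
            p_fdr=pf,
            elapsed=r["elapsed"],
            p_mc=r["p_mc"],
            description=r["term"].description,
        )
        for r, pb, ph, pf in zip(raw, bonf, holm, bh)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
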