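"""Synthetic interaction graphs and term batteries.

Everything in the package is testable offline: this module generates random
tripartite graphs with independent Bernoulli edges per layer, random term
batteries over the combined RNA universe, and the small worked-example
network used throughout the documentation.  Generation is fully seeded and
file emission is byte-deterministic.

Default sizes are a scaled-down analogue of a genome-wide ceRNA graph,
where a circRNA typically reaches a few dozen miRNAs and each mRNA is
targeted by a handful of them; see ``docs/methods.md`` for the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .graph import InteractionGraph
from .statistic import AnnotationTerm

__all__ = ["SyntheticSpec", "example_network", "random_instance", "write_instance"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random tripartite instance.

    ``circ_degree`` is either an exact per-circRNA miRNA degree (int) or an
    independent edge probability (float in [0, 1]).
    """

    n_mirna: int = 40
    n_mrna: int = 150
    n_circ: int = 1
    circ_degree: Union[int, float] = 0.25
    mirna_mrna_density: float = 0.08
    n_terms: int = 20
    term_size_range: Tuple[int, int] = (10, 40)
    seed: int = 0
    plant_first_term: bool = False

    def __post_init__(self):
        if self.n_mirna < 1 or self.n_mrna < 1 or self.n_circ < 1:
            raise ValueError("universe sizes must be at least 1")
        if isinstance(self.circ_degree, float) and not 0 <= self.circ_degree <= 1:
            raise ValueError("circ_degree probability must be in [0, 1]")
        if isinstance(self.circ_degree, int) and not 0 <= self.circ_degree <= self.n_mirna:
            raise ValueError("circ_degree exceeds the miRNA universe")
        if not 0 <= self.mirna_mrna_density <= 1:
            raise ValueError("mirna_mrna_density must be in [0, 1]")
        lo, hi = self.term_size_range
        if lo < 1 or lo > hi:
            raise ValueError("invalid term_size_range")
        if hi > self.n_mirna + self.n_mrna:
            raise ValueError("term size exceeds the combined universe")


def example_network() -> Tuple[InteractionGraph, AnnotationTerm]:
    """The small worked-example network used in the documentation.

    One circRNA sponging all three miRNAs of the graph, five mRNAs, and an
    annotation term covering two miRNAs and three mRNAs.  On this instance
    the statistic is 8 out of 12 paths, its expectation 7.4, and the exact
    p-value 1/2 — small enough to verify every number by hand.
    """
    graph = InteractionGraph(
        mirna_ids=("miR-1", "miR-2", "miR-3"),
        mrna_ids=("G1", "G2", "G3", "G4", "G5"),
        circ_ids=("circ-1",),
        circ_mirna=np.array([[1, 1, 1]]),
        mirna_mrna=np.array(
            [
                [1, 1, 0],
                [1, 1, 1],
                [1, 0, 0],
                [0, 0, 1],
                [0, 1, 1],
            ]
        ),
    )
    term = AnnotationTerm(
        term_id="T1",
        g_mu=np.array([1, 1, 0]),
        g_m=np.array([1, 1, 1, 0, 0]),
        description="example term",
    )
    return graph, term


def random_instance(
    spec: SyntheticSpec,
) -> Tuple[InteractionGraph, List[AnnotationTerm]]:
    """Generate a seeded random graph plus term battery.

    Edges are independent Bernoulli draws per layer; term members are drawn
    uniformly without replacement from the combined miRNA+mRNA universe.
    With ``plant_first_term`` the first circRNA is wired to every miRNA
    member of the first term, so that genuinely low p-values occur.
    """
    rng = np.random.default_rng(spec.seed)
    mirna_ids = tuple(f"miR-{i + 1}" for i in range(spec.n_mirna))
    mrna_ids = tuple(f"GENE{i + 1}" for i in range(spec.n_mrna))
    circ_ids = tuple(f"circ-{i + 1}" for i in range(spec.n_circ))

    if isinstance(spec.circ_degree, int):
        circ_mirna = np.zeros((spec.n_circ, spec.n_mirna), dtype=np.int64)
        for c in range(spec.n_circ):
            idx = rng.choice(spec.n_mirna, size=spec.circ_degree, replace=False)
            circ_mirna[c, idx] = 1
    else:
        circ_mirna = (
            rng.random((spec.n_circ, spec.n_mirna)) < spec.circ_degree
        ).astype(np.int64)
    mirna_mrna = (
        rng.random((spec.n_mrna, spec.n_mirna)) < spec.mirna_mrna_density
    ).astype(np.int64)

    terms: List[AnnotationTerm] = []
    universe = spec.n_mirna + spec.n_mrna
    lo, hi = spec.term_size_range
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        g_mu = np.zeros(spec.n_mirna, dtype=np.int64)
        g_m = np.zeros(spec.n_mrna, dtype=np.int64)
        for m in members:
            if m < spec.n_mirna:
                g_mu[m] = 1
            else:
                g_m[m - spec.n_mirna] = 1
        terms.append(
            AnnotationTerm(
                term_id=f"TERM{t + 1}",
                g_mu=g_mu,
                g_m=g_m,
                description=f"synthetic term {t + 1}",
            )
        )

    if spec.plant_first_term and terms:
        circ_mirna[0] |= terms[0].g_mu

    graph = InteractionGraph(
        mirna_ids=mirna_ids,
        mrna_ids=mrna_ids,
        circ_ids=circ_ids,
        circ_mirna=circ_mirna,
        mirna_mrna=mirna_mrna,
    )
    return graph, terms


def write_instance(
    graph: InteractionGraph,
    terms: List[AnnotationTerm],
    out_dir,
    prefix: str = "instance",
) -> dict:
    """Emit an instance in the exact formats the readers consume.

    Returns a dict with the three file paths (circ–miRNA edges, miRNA–mRNA
    edges, GMT).  Output is deterministic given identical inputs.
    """
    from .io import write_terms  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm_path = out / f"{prefix}.circ_mirna.tsv"
    mm_path = out / f"{prefix}.mirna_mrna.tsv"
    gmt_path = out / f"{prefix}.gmt"
    with cm_path.open("w") as fh:
        for c, row in zip(graph.circ_ids, graph.circ_mirna):
            for m in np.flatnonzero(row):
                fh.write(f"{c}\t{graph.mirna_ids[m]}\n")
    with mm_path.open("w") as fh:
        for j, row in enumerate(graph.mirna_mrna):
            for m in np.flatnonzero(row):
                fh.write(f"{graph.mirna_ids[m]}\t{graph.mrna_ids[j]}\n")
    write_terms(terms, graph, gmt_path)
    return {"circ_mirna": cm_path, "mirna_mrna": mm_path, "gmt": gmt_path}
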