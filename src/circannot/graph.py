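"""Tripartite circRNA–miRNA–mRNA interaction graph.

The graph is directed: edges run from the circRNA layer to the miRNA
layer, and from the miRNA layer to the mRNA layer.  A circRNA acting as a
miRNA sponge therefore reaches a miRNA by a length-1 path and an mRNA by a
length-2 path through a shared miRNA.  All incidence structures are binary;
identifier ordering is fixed at construction time and every vector in the
package is interpreted against that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["InteractionGraph", "CircNeighborhood", "neighborhood"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class InteractionGraph:
    """Binary incidence view of the tripartite interaction network.

    Parameters
    ----------
    mirna_ids, mrna_ids, circ_ids
        Ordered identifier lists; the orderings define the coordinate
        system of every weight/membership vector downstream.
    circ_mirna
        Binary matrix of shape ``(n_circ, n_mirna)``; row *c* marks the
        miRNAs the circRNA *c* interacts with.
    mirna_mrna
        Binary matrix of shape ``(n_mrna, n_mirna)``; row *j* marks the
        miRNAs that target mRNA *j*.
    """

    mirna_ids: tuple
    mrna_ids: tuple
    circ_ids: tuple
    circ_mirna: np.ndarray
    mirna_mrna: np.ndarray
    _circ_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        object.__setattr__(self, "mrna_ids", tuple(self.mrna_ids))
        object.__setattr__(self, "circ_ids", tuple(self.circ_ids))
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.mrna_ids, "mRNA")
        _check_unique(self.circ_ids, "circRNA")
        if len(self.mirna_ids) < 1 or len(self.mrna_ids) < 1:
            raise ValueError("graph needs at least one miRNA and one mRNA")
        cm = np.asarray(self.circ_mirna, dtype=np.int64)
        mm = np.asarray(self.mirna_mrna, dtype=np.int64)
        if cm.shape != (len(self.circ_ids), len(self.mirna_ids)):
            raise ValueError(
                f"circ_mirna shape {cm.shape} does not match "
                f"({len(self.circ_ids)}, {len(self.mirna_ids)})"
            )
        if mm.shape != (len(self.mrna_ids), len(self.mirna_ids)):
            raise ValueError(
                f"mirna_mrna shape {mm.shape} does not match "
                f"({len(self.mrna_ids)}, {len(self.mirna_ids)})"
            )
        for name, arr in (("circ_mirna", cm), ("mirna_mrna", mm)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        object.__setattr__(self, "circ_mirna", cm)
        object.__setattr__(self, "mirna_mrna", mm)
        object.__setattr__(
            self, "_circ_index", {c: i for i, c in enumerate(self.circ_ids)}
        )

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_mrna(self) -> int:
        return len(self.mrna_ids)


@dataclass(frozen=True)
class CircNeighborhood:
    """Per-circRNA weight view of the graph.

    ``mirna_weights`` is the circRNA's incidence row (0/1: does a length-1
    path reach this miRNA).  ``mrna_weights[j]`` counts the distinct
    length-2 paths from the circRNA to mRNA *j*, i.e. the number of shared
    miRNA intermediaries.
    """

    circ_id: str
    mirna_weights: np.ndarray
    mrna_weights: np.ndarray
    mirna_ids: tuple
    mrna_ids: tuple

    def __post_init__(self):
        mu = np.asarray(self.mirna_weights, dtype=np.int64)
        m = np.asarray(self.mrna_weights, dtype=np.int64)
        if not np.isin(mu, (0, 1)).all():
            raise ValueError("mirna_weights entries must be 0 or 1")
        if (m < 0).any() or (m > mu.sum()).any():
            raise ValueError("mrna_weights out of range for the neighborhood")
        object.__setattr__(self, "mirna_weights", mu)
        object.__setattr__(self, "mrna_weights", m)

    @property
    def n_paths(self) -> int:
        """Total number of directed paths leaving the circRNA."""
        return int(self.mirna_weights.sum() + self.mrna_weights.sum())


def neighborhood(graph: InteractionGraph, circ_id: str) -> CircNeighborhood:
    """Derive the weight vectors of one circRNA.

    Raises
    ------
    KeyError
        If ``circ_id`` is not a circRNA of the graph.
    """
    try:
        row = graph._circ_index[circ_id]
    except KeyError:
        raise KeyError(f"circRNA identifier not found in graph: {circ_id!r}") from None
    a = graph.circ_mirna[row]
    return CircNeighborhood(
        circ_id=circ_id,
        mirna_weights=a,
        mrna_weights=graph.mirna_mrna @ a,
        mirna_ids=graph.mirna_ids,
        mrna_ids=graph.mrna_ids,
    )
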