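"""Readers and writers for graphs, term collections and reports.

Edge lists are two-column tab-separated files (an optional header line is
recognized by its tokens); term collections use the GMT dialect (term name,
description, then member symbols).  Identifier matching is exact-string and
case-sensitive throughout — no symbol aliasing or database normalization is
attempted.  All writers are deterministic: stable ordering, fixed float
formatting.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import AnnotationResult
from .graph import InteractionGraph
from .statistic import AnnotationTerm, InfluenceReport

__all__ = [
    "ParseError",
    "read_edge_list",
    "read_graph",
    "read_terms",
    "term_members",
    "write_terms",
    "write_results",
    "write_influence",
    "write_enrichmentmap",
    "write_null_distribution",
]

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "circrna",
    "circ",
    "circ_id",
    "mirna",
    "mirna_id",
    "mrna",
    "mrna_id",
    "source",
    "target",
    "source_id",
    "target_id",
}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


def read_edge_list(path) -> List[Tuple[str, str]]:
    """Read a two-column tab-separated edge list.

    Duplicate edges collapse to one with a warning (incidence is binary);
    self-edges are rejected — the model admits only edges between layers.
    """
    path = Path(path)
    edges: List[Tuple[str, str]] = []
    seen = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated identifiers, "
                    f"got {line!r}"
                )
            src, dst = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (
                src.lower() in _HEADER_TOKENS or dst.lower() in _HEADER_TOKENS
            ):
                continue
            if src == dst:
                raise ParseError(f"{path}:{lineno}: self-edge {src!r} not allowed")
            if (src, dst) in seen:
                logger.warning("%s:%d: duplicate edge %s -> %s", path, lineno, src, dst)
                continue
            seen.add((src, dst))
            edges.append((src, dst))
    if not edges:
        raise ParseError(f"{path}: no edges found")
    return edges


def read_graph(circ_mirna_path, mirna_mrna_path) -> InteractionGraph:
    """Assemble the tripartite graph from the two layer edge lists.

    Universes are unions of the observed identifiers in first-seen order:
    miRNAs from the circRNA layer first, then any further miRNAs appearing
    only as regulators of mRNAs.
    """
    cm_edges = read_edge_list(circ_mirna_path)
    mm_edges = read_edge_list(mirna_mrna_path)

    def ordered_unique(items: Iterable[str]) -> List[str]:
        out, seen = [], set()
        for x in items:
            if x not in seen:
                seen.add(x)
                out.append(x)
        return out

    circ_ids = ordered_unique(c for c, _ in cm_edges)
    mirna_ids = ordered_unique(
        [m for _, m in cm_edges] + [m for m, _ in mm_edges]
    )
    mrna_ids = ordered_unique(g for _, g in mm_edges)

    mu_idx = {m: i for i, m in enumerate(mirna_ids)}
    m_idx = {g: i for i, g in enumerate(mrna_ids)}
    c_idx = {c: i for i, c in enumerate(circ_ids)}

    circ_mirna = np.zeros((len(circ_ids), len(mirna_ids)), dtype=np.int64)
    for c, m in cm_edges:
        circ_mirna[c_idx[c], mu_idx[m]] = 1
    mirna_mrna = np.zeros((len(mrna_ids), len(mirna_ids)), dtype=np.int64)
    for m, g in mm_edges:
        mirna_mrna[m_idx[g], mu_idx[m]] = 1

    return InteractionGraph(
        mirna_ids=mirna_ids,
        mrna_ids=mrna_ids,
        circ_ids=circ_ids,
        circ_mirna=circ_mirna,
        mirna_mrna=mirna_mrna,
    )


def read_terms(gmt_path, graph: InteractionGraph) -> List[AnnotationTerm]:
    """Read a GMT file and match member symbols against the graph universes.

    A symbol may name a miRNA or an mRNA; both universes are probed.
    Members absent from both are counted and logged, never an error — real
    term collections always exceed any one interaction graph.
    """
    gmt_path = Path(gmt_path)
    mu_idx = {m: i for i, m in enumerate(graph.mirna_ids)}
    m_idx = {g: i for i, g in enumerate(graph.mrna_ids)}
    terms: List[AnnotationTerm] = []
    names = set()
    unmatched = 0
    with gmt_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{gmt_path}:{lineno}: GMT line needs at least a name and "
                    f"a description"
                )
            name, description, members = fields[0], fields[1], fields[2:]
            if name in names:
                raise ParseError(f"{gmt_path}:{lineno}: duplicate term {name!r}")
            names.add(name)
            g_mu = np.zeros(graph.n_mirna, dtype=np.int64)
            g_m = np.zeros(graph.n_mrna, dtype=np.int64)
            for sym in members:
                hit = False
                if sym in mu_idx:
                    g_mu[mu_idx[sym]] = 1
                    hit = True
                if sym in m_idx:
                    g_m[m_idx[sym]] = 1
                    hit = True
                if not hit:
                    unmatched += 1
            terms.append(
                AnnotationTerm(term_id=name, g_mu=g_mu, g_m=g_m, description=description)
            )
    if unmatched:
        logger.info(
            "%s: %d member symbols not present in the graph universes",
            gmt_path,
            unmatched,
        )
    return terms


def term_members(term: AnnotationTerm, graph: InteractionGraph) -> List[str]:
    """Member identifiers of a term restricted to the graph universes."""
    mus = [graph.mirna_ids[i] for i in np.flatnonzero(term.g_mu)]
    ms = [graph.mrna_ids[i] for i in np.flatnonzero(term.g_m)]
    return mus + ms


def write_terms(terms: Iterable[AnnotationTerm], graph: InteractionGraph, path) -> None:
    """Write terms as GMT, members restricted to the graph universes."""
    with Path(path).open("w") as fh:
        for t in terms:
            fields = [t.term_id, t.description] + term_members(t, graph)
            fh.write("\t".join(fields) + "\n")


def _fmt_p(p: Optional[Fraction]) -> str:
    # scientific notation, 3 significant digits
    return "NA" if p is None else f"{float(p):.2E}"


_RESULT_COLUMNS = [
    "set_id",
    "size",
    "s",
    "ratio",
    "time_s",
    "p_value",
    "bonferroni",
    "fdr",
]


def write_results(results: Sequence[AnnotationResult], path) -> None:
    """Write the annotation report as TSV.

    Columns: term id, in-graph size, statistic, normalized statistic,
    per-term wall time, exact p-value, Bonferroni- and BH-adjusted
    p-values; a Monte-Carlo column is appended when any row carries one.
    """
    results = list(results)
    with_mc = any(r.p_mc is not None for r in results)
    columns = _RESULT_COLUMNS + (["p_mc"] if with_mc else [])
    with Path(path).open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        if not results:
            logger.warning("writing empty result table to %s", path)
            return
        for r in results:
            row = [
                r.term_id,
                str(r.size),
                str(r.s),
                "NA" if r.ratio is None else f"{float(r.ratio):.12g}",
                f"{r.elapsed:.3g}",
                _fmt_p(r.p),
                _fmt_p(r.p_bonferroni),
                _fmt_p(r.p_fdr),
            ]
            if with_mc:
                row.append(_fmt_p(r.p_mc))
            fh.write("\t".join(row) + "\n")


def write_influence(report: InfluenceReport, path) -> None:
    """Write per-RNA influence as TSV, strongest contributors first.

    Rows are sorted by descending score drop, ties broken by identifier;
    RNAs contributing nothing are kept so the table always covers both
    universes.
    """
    rows = [
        (rid, "miRNA", int(d))
        for rid, d in zip(report.mirna_ids, report.delta_mu)
    ] + [
        (rid, "mRNA", int(d)) for rid, d in zip(report.mrna_ids, report.delta_m)
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    with Path(path).open("w") as fh:
        fh.write("rna_id\tlayer\tdelta\n")
        for rid, layer, d in rows:
            fh.write(f"{rid}\t{layer}\t{d}\n")


def write_enrichmentmap(
    results: Sequence[AnnotationResult],
    terms: Sequence[AnnotationTerm],
    path_prefix,
    graph: InteractionGraph,
) -> Tuple[Path, Path]:
    """Export results in the generic enrichment-results format plus a GMT.

    Produces ``<prefix>.enrichment.txt`` (term, description, p, FDR) and
    ``<prefix>.gmt`` with the reported terms' in-graph members — the two
    files a network-visualization tool needs to lay terms out by overlap.
    Column mapping may still need adjustment in the consuming GUI.
    """
    enr_path = Path(f"{path_prefix}.enrichment.txt")
    gmt_path = Path(f"{path_prefix}.gmt")
    by_id = {t.term_id: t for t in terms}
    reported = [r for r in results if r.term_id in by_id]
    with enr_path.open("w") as fh:
        fh.write("GeneSet\tDescription\tp-value\tFDR\n")
        for r in reported:
            fh.write(
                f"{r.term_id}\t{r.description}\t{_fmt_p(r.p)}\t{_fmt_p(r.p_fdr)}\n"
            )
    write_terms([by_id[r.term_id] for r in reported], graph, gmt_path)
    return enr_path, gmt_path


def write_null_distribution(null, path) -> None:
    """Debug dump of a null distribution as (value, count) TSV."""
    with Path(path).open("w") as fh:
        fh.write("value\tcount\n")
        for v in sorted(null.counts):
            fh.write(f"{v}\t{null.counts[v]}\n")
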