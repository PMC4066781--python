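"""Wiring miRNAs into gene-based pathway graphs.

A miRNA enters a pathway if and only if at least one of its target genes is
already a node of the gene-based network.  Two interaction batches feed the
wiring: reporter-assay validated pairs (wired unconditionally) and in-silico
predictions, which are first filtered by TargetScan P_ct and then by a
dataset-specific Pearson correlation screen.  Both correlated and
anti-correlated interactions are kept: the sign of the miRNA–target
relationship depends on the surrounding pathway topology, so the filter is
on |r|.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_model import (MIRNA, ExpressionDataset, InteractionRecord,
                          PathwayGraph)

logger = logging.getLogger(__name__)

#: relation label carried by wired miRNA→target edges in SIF output
MIRNA_RELATION = "mirna-target"


def select_predictions(records: Sequence[InteractionRecord],
                       pct_min: float = 0.8) -> list[InteractionRecord]:
    """Keep predicted records with P_ct ≥ ``pct_min`` (boundary inclusive)."""
    out = []
    for rec in records:
        if rec.pct is None:
            raise ValueError(f"predicted record {rec.key} lacks pct")
        if rec.pct >= pct_min:
            out.append(rec)
    return out


def correlation_filter(records: Sequence[InteractionRecord],
                       mirna_expr: ExpressionDataset,
                       gene_expr: ExpressionDataset,
                       r_min: float = 0.4,
                       q_max: float = 0.05) -> list[InteractionRecord]:
    """Expression-correlation screen for predicted miRNA–target pairs.

    For every record whose miRNA and gene are measured, the Pearson r is
    computed across all samples pooled (the screen precedes any group
    comparison); the two-sided p-value uses the t approximation
    ``t = r·sqrt((n−2)/(1−r²))`` with n−2 df, and p-values are converted
    to q-values by Benjamini–Hochberg across all tested records.  Records
    pass when ``|r| ≥ r_min`` and ``q ≤ q_max`` (both inclusive).
    Zero-variance vectors and unmeasured features drop the record.
    """
    if set(mirna_expr.samples) != set(gene_expr.samples):
        raise ValueError("miRNA and gene expression sample sets differ")
    # align gene columns onto the miRNA sample order so the filter is
    # invariant to simultaneous sample reordering
    samples = list(mirna_expr.samples)
    gvals = gene_expr.values.loc[:, samples]
    mvals = mirna_expr.values
    n = len(samples)
    if n < 3:
        raise ValueError("correlation filter needs at least 3 samples")

    tested: list[InteractionRecord] = []
    rs: list[float] = []
    ps: list[float] = []
    for rec in records:
        if rec.mirna not in mvals.index or rec.target not in gvals.index:
            logger.warning("correlation_filter: %s -> %s not measured, "
                           "record dropped", rec.mirna, rec.target)
            continue
        x = mvals.loc[rec.mirna].to_numpy(dtype=float)
        y = gvals.loc[rec.target].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("correlation_filter: zero-variance vector for "
                           "%s -> %s, record dropped", rec.mirna, rec.target)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
        tested.append(rec)
        rs.append(r)
        ps.append(min(p, 1.0))

    if not tested:
        return []
    qs = multipletests(ps, method="fdr_bh")[1]
    out = []
    for rec, r, q in zip(tested, rs, qs):
        if abs(r) >= r_min and q <= q_max:
            out.append(InteractionRecord(rec.mirna, rec.target, rec.evidence,
                                         pct=rec.pct, r=r, q=float(q)))
    return out


def merge_interactions(validated: Sequence[InteractionRecord],
                       predicted: Sequence[InteractionRecord]
                       ) -> list[InteractionRecord]:
    """Union of the two batches keyed by (mirna, target).

    Pairs present in both inputs get evidence ``both`` and keep the
    prediction's pct/r/q statistics.
    """
    merged: dict[tuple[str, str], InteractionRecord] = {}
    for rec in validated:
        merged[rec.key] = InteractionRecord(rec.mirna, rec.target, "validated")
    n_both = 0
    for rec in predicted:
        if rec.key in merged:
            merged[rec.key] = InteractionRecord(
                rec.mirna, rec.target, "both", pct=rec.pct, r=rec.r, q=rec.q)
            n_both += 1
        else:
            merged[rec.key] = InteractionRecord(
                rec.mirna, rec.target, "predicted",
                pct=rec.pct, r=rec.r, q=rec.q)
    counts = {"validated": len(validated) - n_both,
              "predicted": len(predicted) - n_both, "both": n_both}
    logger.info("merged interactions: %d validated-only, %d predicted-only, "
                "%d both", counts["validated"], counts["predicted"],
                counts["both"])
    return [merged[k] for k in sorted(merged)]


def wire_mirnas(graph: PathwayGraph,
                records: Sequence[InteractionRecord]) -> PathwayGraph:
    """Expand a pathway with miRNA nodes and miRNA→target edges.

    A miRNA is added iff at least one of its targets is a gene node of the
    graph; one directed edge per present target, with provenance from the
    record's evidence class.  Gene nodes and gene–gene edges are untouched,
    and wiring is idempotent.
    """
    wired = graph.copy()
    genes = set(graph.genes)
    for rec in sorted(records, key=lambda r: r.key):
        if rec.target not in genes:
            continue
        if rec.mirna not in wired:
            wired.add_node(rec.mirna, MIRNA)
        wired.add_edge(rec.mirna, rec.target, MIRNA_RELATION,
                       provenance=rec.evidence)
    return wired


def wiring_summary(wired: Mapping[str, PathwayGraph]) -> pd.DataFrame:
    """Per-pathway composition table after wiring.

    The ``ratio`` column follows the reporting convention
    ``(total nodes) / (gene count)`` truncated — not rounded — to one
    decimal.  (Such tables are conventionally labelled miRNAs-over-genes,
    but the printed values follow the totals-over-genes truncation
    convention implemented here.)
    """
    rows = []
    for pid in sorted(wired):
        g = wired[pid]
        counts = g.edge_counts()
        n_genes = len(g.genes)
        n_total = len(g)
        rows.append({
            "pathway_id": pid,
            "n_genes": n_genes,
            "n_mirnas": len(g.mirnas),
            "n_total": n_total,
            "n_mirna_gene_edges": counts["mirna_gene"],
            "n_gene_gene_edges": counts["gene_gene"],
            "ratio": format_ratio(n_genes, n_total),
        })
    return pd.DataFrame(rows, columns=["pathway_id", "n_genes", "n_mirnas",
                                       "n_total", "n_mirna_gene_edges",
                                       "n_gene_gene_edges", "ratio"])


def format_ratio(n_genes: int, n_total: int) -> str:
    """Totals-over-genes ratio truncated to one decimal, as printed text."""
    if n_genes <= 0:
        raise ValueError("gene count must be positive")
    tenths = (10 * n_total) // n_genes
    return f"{tenths // 10}.{tenths % 10}"


def database_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean and median of each per-pathway count across a database."""
    cols = ["n_genes", "n_mirnas", "n_total",
            "n_mirna_gene_edges", "n_gene_gene_edges"]
    return pd.DataFrame({"mean": summary[cols].mean(),
                         "median": summary[cols].median()})
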