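"""End-to-end orchestration: wire → test → select → paths → meta-pathway.

The stages share a single user seed expanded into independent per-stage
random streams (pathway tests, clique tests, meta-pathway re-analysis), so
changing the number of permutations in one stage never perturbs another
stage's draws, and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .graph_model import (Config, ExpressionDataset, InteractionRecord,
                          PathwayGraph)
from .ggm_testing import results_table, select_pathways, test_pathway
from .meta_pathway import analyze_metapathway, build_metapathway
from .mirna_wiring import (correlation_filter, merge_interactions,
                           select_predictions, wire_mirnas, wiring_summary)
from .path_finder import PathResult, find_best_path

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    wired: dict[str, PathwayGraph]
    interactions: list[InteractionRecord]
    combined_expr: ExpressionDataset
    pathway_results: pd.DataFrame
    selected: list[str]
    best_paths: dict[str, PathResult]
    meta_graph: Optional[PathwayGraph]
    meta_paths: list[PathResult]
    wiring_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-stage generators derived from one seed."""
    ss = np.random.SeedSequence(seed)
    names = ("pathway_tests", "clique_tests", "meta_analysis")
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def build_interactions(validated: Optional[Sequence[InteractionRecord]],
                       predicted: Optional[Sequence[InteractionRecord]],
                       gene_expr: ExpressionDataset,
                       mirna_expr: Optional[ExpressionDataset],
                       config: Config) -> list[InteractionRecord]:
    """Dataset-specific interaction set: validated ∪ filtered predictions.

    Validated pairs are kept unconditionally; predictions pass the P_ct
    threshold and then the pooled-sample correlation screen.
    """
    validated = list(validated) if validated else []
    filtered: list[InteractionRecord] = []
    if predicted:
        kept = select_predictions(predicted, config.pct_min)
        if mirna_expr is None:
            raise ValueError("predicted interactions require miRNA "
                             "expression for the correlation filter")
        filtered = correlation_filter(kept, mirna_expr, gene_expr,
                                      config.r_min, config.q_max_corr)
    return merge_interactions(validated, filtered)


def run_pipeline(graphs: Mapping[str, PathwayGraph],
                 gene_expr: ExpressionDataset,
                 mirna_expr: Optional[ExpressionDataset] = None,
                 validated: Optional[Sequence[InteractionRecord]] = None,
                 predicted: Optional[Sequence[InteractionRecord]] = None,
                 config: Optional[Config] = None) -> PipelineResult:
    """Run all stages on in-memory inputs and return every stage's output.

    ``graphs`` are gene-only pathway graphs; the miRNA layer is optional —
    without it the analysis runs on the gene graphs alone.
    """
    config = config or Config()
    rngs = stage_rngs(config.seed)

    # step 1: wiring
    interactions: list[InteractionRecord] = []
    if mirna_expr is not None and (validated or predicted):
        interactions = build_interactions(validated, predicted,
                                          gene_expr, mirna_expr, config)
    wired: dict[str, PathwayGraph] = {}
    for pid in sorted(graphs):
        g = wire_mirnas(graphs[pid], interactions)
        g.pathway_id = str(pid)  # mapping key is the canonical pathway id
        wired[str(pid)] = g
    wtable = wiring_summary(wired)

    expr = (gene_expr.concat_rows(mirna_expr) if mirna_expr is not None
            else gene_expr)
    if expr.groups is None:
        raise ValueError("expression dataset has no group labels")

    # step 2: pathway-level tests and selection
    results = []
    for pid in sorted(wired):
        res = test_pathway(wired[pid], expr, config, rngs["pathway_tests"])
        if res is not None:
            results.append(res)
    table = results_table(results, config)
    selected = select_pathways(table, config.alpha_pathway,
                               config.selection_mode)

    # step 3: best path per selected pathway
    best: dict[str, PathResult] = {}
    for pid in selected:
        path = find_best_path(wired[pid], expr, config, rngs["clique_tests"])
        if path is not None:
            best[pid] = path

    # steps 4-5: meta-pathway construction and re-analysis
    meta_graph = None
    meta_paths: list[PathResult] = []
    if best:
        meta_graph = build_metapathway(list(best.values()), wired)
        measured = set(meta_graph.nodes) & set(expr.features)
        if len(measured) >= 2:
            meta_paths = analyze_metapathway(meta_graph, expr, config,
                                             rngs["meta_analysis"])
        else:
            logger.warning("meta-pathway too small to re-analyse")

    return PipelineResult(wired=wired, interactions=interactions,
                          combined_expr=expr, pathway_results=table,
                          selected=selected, best_paths=best,
                          meta_graph=meta_graph, meta_paths=meta_paths,
                          wiring_table=wtable)
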