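"""Meta-pathway construction and re-analysis.

Pathway annotations overlap heavily, so per-pathway best paths can be
redundant or truncated (a signal that starts in one pathway and continues in
another).  The meta-pathway is the non-redundant union of all top-scored
paths: node identity merges shared genes/miRNAs across pathways, and each
path contributes the edges of its source wired pathway induced on the path's
node set (the induced-subgraph choice preserves clique structure; the union
of bare chain edges would not).  Every meta edge remembers its source
pathways.  The combined graph — possibly disconnected — is then decomposed
and path-analysed again, and all candidate paths are pooled and ranked by
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .graph_model import Config, ExpressionDataset, PathwayGraph
from .ggm_testing import decompose, restrict_to_measured
from .path_finder import (PathResult, clique_pvalues, enumerate_paths,
                          make_path_result)

logger = logging.getLogger(__name__)

META_ID = "meta"


def build_metapathway(best_paths: Sequence[PathResult],
                      wired: Mapping[str, PathwayGraph]) -> PathwayGraph:
    """Non-redundant union of top-scored paths into one meta-pathway graph.

    Nodes merge by identifier; each path contributes the induced edges of
    its source wired pathway on the path's node set; duplicate nodes and
    edges appear once, and nodes/edges carry the sorted list of source
    pathways in their ``source_pathways`` attribute.
    """
    if not best_paths:
        raise ValueError("no best paths to combine")
    meta = PathwayGraph(META_ID)
    node_src: dict[str, set[str]] = {}
    edge_src: dict[tuple[str, str, str], set[str]] = {}
    for path in sorted(best_paths, key=lambda p: p.pathway_id):
        source = wired[path.pathway_id]
        induced = source.subgraph_on(path.nodes)
        for n in induced.nodes:
            if n not in meta:
                meta.add_node(n, source.node_type(n))
            node_src.setdefault(n, set()).add(path.pathway_id)
        for u, v, rel, prov in induced.edges():
            if (u, v, rel) not in edge_src:
                meta.add_edge(u, v, rel, provenance=prov)
            edge_src.setdefault((u, v, rel), set()).add(path.pathway_id)
    for n, src in node_src.items():
        meta._g.nodes[n]["source_pathways"] = tuple(sorted(src))
    for (u, v, rel), src in edge_src.items():
        meta._g.edges[u, v].setdefault("source_pathways", {})[rel] = \
            tuple(sorted(src))
    # induced subgraphs may strand a miRNA whose targets fell outside a
    # path, so the miRNA-regulation invariant is not enforced here
    meta.validate(require_mirna_regulation=False)
    return meta


def edge_sources(meta: PathwayGraph) -> dict[tuple[str, str, str],
                                             tuple[str, ...]]:
    """Map each meta edge triple to its source pathway ids."""
    out = {}
    for u, v, rel, _ in meta.edges():
        src = meta._g.edges[u, v].get("source_pathways", {}).get(rel, ())
        out[(u, v, rel)] = tuple(src)
    return out


def analyze_metapathway(meta: PathwayGraph, expr: ExpressionDataset,
                        config: Config, rng: np.random.Generator
                        ) -> list[PathResult]:
    """Clique-test and rank all paths of the meta-pathway.

    Each connected component of the measured skeleton is decomposed and
    analysed separately (the union of paths can legitimately be
    disconnected); candidate paths are pooled and ranked by descending
    score with the same tie-breaks as per-pathway best-path selection.
    """
    sub = restrict_to_measured(meta, expr)
    if len(sub) < 2:
        raise ValueError("meta-pathway has fewer than 2 measured features")
    skeleton = sub.skeleton()
    pooled: list[PathResult] = []
    for comp in sorted(nx.connected_components(skeleton), key=sorted):
        comp_graph = sub.subgraph_on(comp)
        decomp = decompose(comp_graph)
        jt = decomp.junction_tree
        results = clique_pvalues(jt, expr, config, rng)
        candidates = enumerate_paths(jt, results, config.max_gaps)
        pooled.extend(make_path_result(META_ID, p, results, config)
                      for p in candidates)
    if not pooled:
        logger.warning("meta-pathway: no significant clique anywhere; "
                       "empty ranking")
        return []
    pooled.sort(key=lambda r: (-r.score, -r.n_cliques, r.nodes))
    return pooled


@dataclass
class ContainmentReport:
    """Comparison of the gene-only and the integrated meta-pathway."""

    gene_only_nodes: tuple[str, ...]
    integrated_nodes: tuple[str, ...]
    contained: bool
    gene_only_best_rank_in_integrated: Optional[int]  # 1-based, None if absent


def gene_only_comparison(graphs: Mapping[str, PathwayGraph],
                         gene_expr: ExpressionDataset,
                         mirna_expr: Optional[ExpressionDataset],
                         validated, predicted, config: Config
                         ) -> tuple[Optional[PathwayGraph],
                                    list[PathResult], ContainmentReport]:
    """Run the pipeline with and without the miRNA layer and compare.

    Reports whether the gene-only meta-pathway node set is contained in
    the integrated one, and at which rank of the integrated meta-path
    list the gene-only best path's node set first appears (as a subset).
    """
    from .pipeline import run_pipeline

    integrated = run_pipeline(graphs, gene_expr, mirna_expr=mirna_expr,
                              validated=validated, predicted=predicted,
                              config=config)
    gene_only = run_pipeline(graphs, gene_expr, mirna_expr=None,
                             validated=None, predicted=None, config=config)

    g_nodes = (tuple(gene_only.meta_graph.nodes)
               if gene_only.meta_graph is not None else ())
    i_nodes = (tuple(integrated.meta_graph.nodes)
               if integrated.meta_graph is not None else ())
    contained = set(g_nodes) <= set(i_nodes)
    rank = None
    if gene_only.meta_paths and integrated.meta_paths:
        target = set(gene_only.meta_paths[0].nodes)
        for i, path in enumerate(integrated.meta_paths, start=1):
            if target <= set(path.nodes):
                rank = i
                break
    report = ContainmentReport(g_nodes, i_nodes, contained, rank)
    return gene_only.meta_graph, gene_only.meta_paths, report
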