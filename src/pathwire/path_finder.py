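"""Clique-level testing and best-path identification on the junction tree.

Each maximal clique is tested independently for group differences in means
and covariances (a clique is complete, so the saturated model applies) with
the same permutation machinery as the whole-pathway test.  A *path* is a
chain of adjacent junction-tree cliques whose endpoints are significant and
which contains at most ``max_gaps`` non-significant interior cliques
("gaps").  The path score rewards significant cliques and penalises gaps:

    score = Σ_{significant cliques} −log10(p) − γ · (#gaps)

with γ defaulting to −log10(alpha_clique), so one gap cancels exactly one
boundary-significant clique.  The highest-scoring path per pathway is the
reported circuit candidate.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .graph_model import Config, ExpressionDataset, PathwayGraph
from .ggm_testing import (JunctionTree, decompose, joint_permutation_test,
                          _membership_matrix, restrict_to_measured)

logger = logging.getLogger(__name__)

Clique = tuple[str, ...]


@dataclass
class CliqueResult:
    """Permutation test outcome for one clique."""

    clique: Clique
    p_mean: float
    p_var: float
    p_combined: float
    significant: bool


@dataclass
class PathResult:
    """A scored chain of junction-tree cliques."""

    pathway_id: str
    cliques: tuple[Clique, ...]
    gaps: int
    nodes: tuple[str, ...]
    score: float
    clique_pvalues: tuple[float, ...]

    @property
    def n_cliques(self) -> int:
        return len(self.cliques)


def _combine(p_mean: float, p_var: float, mode: str) -> float:
    if mode == "mean":
        return p_mean
    if mode == "variance":
        return p_var
    return min(p_mean, p_var)


def clique_pvalues(jt: JunctionTree, expr: ExpressionDataset,
                   config: Config, rng: np.random.Generator
                   ) -> dict[Clique, CliqueResult]:
    """Test every clique independently, reusing one set of permutations.

    Clique significance combines the two tests per ``config.clique_mode``
    ("either" takes min(p_mean, p_var), mirroring the mean-and/or-variance
    reading).  Cliques at least as large as the smaller group get the
    ridge automatically.
    """
    labels = expr.group_mask()
    n1 = int(labels.sum())
    n2 = labels.size - n1
    M = _membership_matrix(labels, config.permutations, rng)
    out: dict[Clique, CliqueResult] = {}
    for clique in jt.cliques:
        X = expr.matrix(clique)
        idx = np.arange(len(clique))
        ridge = config.ridge_lambda if min(n1, n2) <= len(clique) else 0.0
        if ridge and config.ridge_lambda == 0:
            logger.warning("clique %s larger than the smaller group; "
                           "ridge auto-enabled", clique)
        res = joint_permutation_test(X, labels, [(idx, +1)],
                                     config.permutations, rng,
                                     ridge, membership=M)
        pc = _combine(res.p_mean, res.p_var, config.clique_mode)
        out[clique] = CliqueResult(clique, res.p_mean, res.p_var, pc,
                                   pc <= config.alpha_clique)
    return out


def enumerate_paths(jt: JunctionTree,
                    results: Mapping[Clique, CliqueResult],
                    max_gaps: int = 1) -> list[tuple[Clique, ...]]:
    """All candidate clique chains with significant endpoints and ≤ max_gaps.

    Candidates are the unique tree paths between pairs of significant
    cliques (trimming endpoint gaps can only raise the score, so paths
    are enumerated directly between significant endpoints) plus every
    single significant clique; interior non-significant cliques count as
    gaps.  Paths are computed per connected component of the forest.
    """
    significant = [c for c in jt.cliques if results[c].significant]
    candidates: list[tuple[Clique, ...]] = [(c,) for c in significant]
    for c1, c2 in itertools.combinations(significant, 2):
        if not nx.has_path(jt.tree, c1, c2):
            continue
        path = tuple(nx.shortest_path(jt.tree, c1, c2))
        gaps = sum(1 for c in path[1:-1] if not results[c].significant)
        if gaps <= max_gaps:
            candidates.append(path)
    return candidates


def path_gaps(path: Sequence[Clique],
              results: Mapping[Clique, CliqueResult]) -> int:
    return sum(1 for c in path if not results[c].significant)


def path_nodes(path: Sequence[Clique]) -> tuple[str, ...]:
    """Union of clique node sets in path order, deduplicated."""
    seen: list[str] = []
    for clique in path:
        for n in clique:
            if n not in seen:
                seen.append(n)
    return tuple(seen)


def score_path(path: Sequence[Clique],
               results: Mapping[Clique, CliqueResult],
               config: Config) -> float:
    """Sum of −log10(p) over significant cliques minus γ per gap."""
    score = 0.0
    for clique in path:
        res = results[clique]
        if res.significant:
            score += -math.log10(res.p_combined)
    score -= config.effective_gap_penalty * path_gaps(path, results)
    return score


def make_path_result(pathway_id: str, path: Sequence[Clique],
                     results: Mapping[Clique, CliqueResult],
                     config: Config) -> PathResult:
    return PathResult(
        pathway_id=pathway_id, cliques=tuple(path),
        gaps=path_gaps(path, results), nodes=path_nodes(path),
        score=score_path(path, results, config),
        clique_pvalues=tuple(results[c].p_combined for c in path))


def best_path(pathway_id: str,
              candidates: Sequence[Sequence[Clique]],
              results: Mapping[Clique, CliqueResult],
              config: Config) -> Optional[PathResult]:
    """Maximum-score candidate; ties break by more cliques, then by the
    lexicographically smallest node list.  ``None`` when no clique is
    significant."""
    scored = [make_path_result(pathway_id, p, results, config)
              for p in candidates]
    if not scored:
        logger.info("pathway %s: no significant clique, no path reported",
                    pathway_id)
        return None
    scored.sort(key=lambda r: (-r.score, -r.n_cliques, r.nodes))
    return scored[0]


def find_best_path(graph: PathwayGraph, expr: ExpressionDataset,
                   config: Config, rng: np.random.Generator
                   ) -> Optional[PathResult]:
    """Decompose a wired pathway and return its top-scored path."""
    sub = restrict_to_measured(graph, expr)
    if len(sub) < 1:
        return None
    decomp = decompose(sub)
    jt = decomp.junction_tree
    results = clique_pvalues(jt, expr, config, rng)
    candidates = enumerate_paths(jt, results, config.max_gaps)
    return best_path(graph.pathway_id, candidates, results, config)


def validate_path(path: Sequence[Clique], jt: JunctionTree,
                  results: Mapping[Clique, CliqueResult],
                  max_gaps: int) -> bool:
    """Independent validity check: endpoint significance, tree adjacency,
    gap bound."""
    if not path:
        return False
    if not (results[path[0]].significant and results[path[-1]].significant):
        return False
    for a, b in zip(path, path[1:]):
        if not jt.tree.has_edge(a, b):
            return False
    return path_gaps(path, results) <= max_gaps
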