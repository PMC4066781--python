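"""Topological two-group test engine based on decomposable Gaussian graphical models.

A wired pathway is moralized, triangulated (min-fill heuristic with
deterministic tie-breaks) and decomposed into maximal cliques organised in a
junction tree satisfying the running intersection property.  On that
decomposition two permutation tests compare the sample groups:

* a Hotelling-type statistic for equality of multivariate means,
  ``T² = (n1·n2/n) · d' K̂ d`` with ``K̂`` the decomposable-model MLE of the
  pooled within-group concentration matrix, and
* a Gaussian likelihood-ratio statistic for equality of covariance matrices,
  ``Λ = n·logdet Σ̂_pooled − n1·logdet Σ̂₁ − n2·logdet Σ̂₂``, every logdet
  evaluated through the clique/separator factorisation
  ``logdet Σ̂ = Σ_C logdet S_C − Σ_S logdet S_S``.

Covariance MLEs use denominator ``n_g`` (not ``n_g − 1``); that convention
makes Λ a true nested-model LRT and hence non-negative when no ridge is
applied.  When the smaller group is not larger than the widest clique the
clique/separator marginals are ridge-regularised by ``λ·mean(diag)·I``.

Significance comes from permutation of the group labels: both statistics are
recomputed over B uniform relabelings preserving the group sizes and
``p = (1 + #{stat_b ≥ stat_obs}) / (B + 1)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.moral import moral_graph
from statsmodels.stats.multitest import multipletests

from .graph_model import Config, ExpressionDataset, PathwayGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Moralization and triangulation
# ---------------------------------------------------------------------------

def moralize(graph) -> nx.Graph:
    """Moral graph: marry the parents of every node, drop directions.

    Accepts a :class:`PathwayGraph` or a directed networkx graph; cycles
    are allowed (cyclic edges simply become undirected).
    """
    if isinstance(graph, PathwayGraph):
        digraph = graph.directed()
    elif graph.is_directed():
        digraph = graph
    else:
        # already undirected: moralization is the identity
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from(graph.edges)
        return g
    moral = moral_graph(digraph)
    moral.remove_edges_from(nx.selfloop_edges(moral))
    return moral


@dataclass
class ChordalDecomposition:
    """Chordal cover of an undirected graph with its clique/separator system.

    ``nodes`` fixes the variable order used by every matrix aligned with
    this decomposition.  ``separators`` lists the junction-tree edge
    separators with multiplicity, which is the multiset the decomposable
    MLE subtracts.
    """

    nodes: tuple[str, ...]
    moral: nx.Graph
    chordal: nx.Graph
    fill_edges: tuple[tuple[str, str], ...]
    elimination_order: tuple[str, ...]
    cliques: tuple[tuple[str, ...], ...]

    @cached_property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @cached_property
    def junction_tree(self) -> "JunctionTree":
        return build_junction_tree(self)

    @cached_property
    def separators(self) -> tuple[tuple[str, ...], ...]:
        return tuple(sorted(d["separator"] for _, _, d in
                            self.junction_tree.tree.edges(data=True)))

    @property
    def max_clique_size(self) -> int:
        return max((len(c) for c in self.cliques), default=0)

    def blocks(self) -> list[tuple[np.ndarray, int]]:
        """(index array, sign) pairs: +1 per clique, −1 per separator."""
        idx = self.index
        out = [(np.fromiter((idx[n] for n in c), dtype=int), +1)
               for c in self.cliques]
        out += [(np.fromiter((idx[n] for n in s), dtype=int), -1)
                for s in self.separators if s]
        return out


def triangulate(ugraph: nx.Graph) -> ChordalDecomposition:
    """Chordal cover by min-fill elimination with deterministic tie-breaks.

    At each step the eliminated node minimises the number of fill edges
    among its remaining neighbours; ties break by smaller degree, then by
    lexicographic node id.  Maximal cliques are extracted from the
    elimination order of the filled graph.
    """
    nodes = tuple(sorted(ugraph.nodes))
    work = {n: set(ugraph.neighbors(n)) - {n} for n in nodes}
    filled = nx.Graph()
    filled.add_nodes_from(nodes)
    filled.add_edges_from((u, v) for u, v in ugraph.edges if u != v)
    fill_edges: list[tuple[str, str]] = []
    order: list[str] = []
    remaining = set(nodes)

    def fill_count(n: str) -> int:
        nbrs = list(work[n])
        return sum(1 for a, b in itertools.combinations(nbrs, 2)
                   if b not in work[a])

    while remaining:
        best = min(remaining, key=lambda n: (fill_count(n), len(work[n]), n))
        nbrs = sorted(work[best])
        for a, b in itertools.combinations(nbrs, 2):
            if b not in work[a]:
                work[a].add(b)
                work[b].add(a)
                filled.add_edge(a, b)
                fill_edges.append((min(a, b), max(a, b)))
        for a in nbrs:
            work[a].discard(best)
        del work[best]
        remaining.discard(best)
        order.append(best)

    cliques = _cliques_from_order(filled, order)
    return ChordalDecomposition(
        nodes=nodes, moral=ugraph, chordal=filled,
        fill_edges=tuple(sorted(set(fill_edges))),
        elimination_order=tuple(order), cliques=cliques)


def _cliques_from_order(chordal: nx.Graph,
                        order: Sequence[str]) -> tuple[tuple[str, ...], ...]:
    """Maximal cliques of a chordal graph from a perfect elimination order."""
    pos = {n: i for i, n in enumerate(order)}
    candidates = []
    for n in order:
        clique = frozenset({n} | {m for m in chordal.neighbors(n)
                                  if pos[m] > pos[n]})
        candidates.append(clique)
    maximal = []
    for c in candidates:
        if not any(c < other for other in candidates):
            maximal.append(c)
    unique = sorted({tuple(sorted(c)) for c in maximal})
    return tuple(unique)


def decompose(graph) -> ChordalDecomposition:
    """Moralize then triangulate in one call."""
    return triangulate(moralize(graph))


# ---------------------------------------------------------------------------
# Junction tree
# ---------------------------------------------------------------------------

@dataclass
class JunctionTree:
    """Forest of cliques (one tree per connected component) carrying the RIP.

    Tree nodes are sorted clique tuples; each edge stores its separator
    (clique intersection) and weight (separator size).
    """

    tree: nx.Graph

    @property
    def cliques(self) -> list[tuple[str, ...]]:
        return sorted(self.tree.nodes)

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.tree)

    def separator(self, c1, c2) -> tuple[str, ...]:
        return self.tree.edges[c1, c2]["separator"]

    def verify_rip(self) -> None:
        """Exhaustively check the running intersection property.

        For any two cliques in the same tree, every clique on the unique
        path between them must contain their intersection.
        """
        for comp in nx.connected_components(self.tree):
            comp = sorted(comp)
            for c1, c2 in itertools.combinations(comp, 2):
                inter = set(c1) & set(c2)
                if not inter:
                    continue
                path = nx.shortest_path(self.tree, c1, c2)
                for c in path:
                    if not inter <= set(c):
                        raise RuntimeError(
                            f"running intersection property violated between "
                            f"{c1} and {c2} at {c}")


def build_junction_tree(decomp: ChordalDecomposition) -> JunctionTree:
    """Maximum-weight spanning forest of the clique graph.

    Edge weight is the separator size |C_i ∩ C_j|; Kruskal with ties
    broken by the lexicographically smallest clique pair.  The running
    intersection property is verified post-construction.
    """
    cliques = list(decomp.cliques)
    tree = nx.Graph()
    tree.add_nodes_from(cliques)
    candidates = []
    for c1, c2 in itertools.combinations(cliques, 2):
        sep = tuple(sorted(set(c1) & set(c2)))
        if sep:
            candidates.append((-len(sep), c1, c2, sep))
    candidates.sort()
    uf = {c: c for c in cliques}

    def find(c):
        while uf[c] != c:
            uf[c] = uf[uf[c]]
            c = uf[c]
        return c

    for negw, c1, c2, sep in candidates:
        r1, r2 = find(c1), find(c2)
        if r1 != r2:
            uf[r1] = r2
            tree.add_edge(c1, c2, separator=sep, weight=-negw)

    jt = JunctionTree(tree)
    jt.verify_rip()
    return jt


# ---------------------------------------------------------------------------
# Decomposable-model estimation
# ---------------------------------------------------------------------------

class SingularMarginalError(np.linalg.LinAlgError):
    """A clique or separator marginal is singular and no ridge is active."""


def _block_inv_logdet(M: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    if ridge > 0:
        M = M + ridge * np.mean(np.diag(M)) * np.eye(M.shape[0])
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise SingularMarginalError(
            "singular clique/separator marginal; enable ridge "
            "regularization (ridge_lambda > 0)")
    return np.linalg.inv(M), logdet


def decomposable_mle(S: np.ndarray, decomp: ChordalDecomposition,
                     ridge_lambda: float = 0.0,
                     return_sigma: bool = True
                     ) -> tuple[Optional[np.ndarray], np.ndarray, float]:
    """Closed-form MLE of a decomposable Gaussian model from a sample covariance.

    ``K̂ = Σ_C [(S_C)⁻¹]⁰ − Σ_S [(S_S)⁻¹]⁰`` (zero-padded blocks) and
    ``logdet Σ̂ = Σ_C logdet S_C − Σ_S logdet S_S``.  ``S`` must be aligned
    with ``decomp.nodes``.  Returns ``(Σ̂, K̂, logdet Σ̂)``; Σ̂ is only
    materialised when ``return_sigma``.
    """
    p = len(decomp.nodes)
    if S.shape != (p, p):
        raise ValueError(f"S has shape {S.shape}, expected ({p}, {p})")
    K = np.zeros((p, p))
    logdet = 0.0
    for idx, sign in decomp.blocks():
        inv, ld = _block_inv_logdet(S[np.ix_(idx, idx)], ridge_lambda)
        K[np.ix_(idx, idx)] += sign * inv
        logdet += sign * ld
    K = (K + K.T) / 2.0
    sigma = np.linalg.inv(K) if return_sigma else None
    return sigma, K, logdet


def _group_cov_mle(X: np.ndarray) -> np.ndarray:
    """Covariance MLE (denominator n) of a features × samples matrix."""
    n = X.shape[1]
    c = X - X.mean(axis=1, keepdims=True)
    return (c @ c.T) / n


def mean_statistic(X1: np.ndarray, X2: np.ndarray,
                   decomp: ChordalDecomposition,
                   ridge_lambda: float = 0.0) -> float:
    """Hotelling-type T² under the decomposable model.

    ``X1``/``X2`` are features × samples, rows aligned with
    ``decomp.nodes``.  The pooled within-group covariance is the
    sample-size-weighted average of the per-group MLEs.
    """
    n1, n2 = X1.shape[1], X2.shape[1]
    n = n1 + n2
    d = X1.mean(axis=1) - X2.mean(axis=1)
    S_pooled = (n1 * _group_cov_mle(X1) + n2 * _group_cov_mle(X2)) / n
    _, K, _ = decomposable_mle(S_pooled, decomp, ridge_lambda,
                               return_sigma=False)
    return float(n1 * n2 / n * d @ K @ d)


def concentration_statistic(X1: np.ndarray, X2: np.ndarray,
                            decomp: ChordalDecomposition,
                            ridge_lambda: float = 0.0) -> float:
    """LRT statistic for equality of covariance matrices under the model."""
    n1, n2 = X1.shape[1], X2.shape[1]
    n = n1 + n2
    S1, S2 = _group_cov_mle(X1), _group_cov_mle(X2)
    S_pooled = (n1 * S1 + n2 * S2) / n
    ld = [decomposable_mle(S, decomp, ridge_lambda, return_sigma=False)[2]
          for S in (S_pooled, S1, S2)]
    return float(n * ld[0] - n1 * ld[1] - n2 * ld[2])


# ---------------------------------------------------------------------------
# Permutation machinery (vectorised over relabelings)
# ---------------------------------------------------------------------------

def permutation_pvalue(statistic: Callable[[np.ndarray, np.ndarray], float],
                       X: np.ndarray, labels: np.ndarray, B: int,
                       rng: np.random.Generator) -> float:
    """Generic permutation p-value for a two-sample statistic.

    ``labels`` is a boolean mask (group 1) over the columns of ``X``;
    permutations are uniform label shuffles preserving the group sizes.
    ``p = (1 + #{stat_b ≥ stat_obs}) / (B + 1)``.
    """
    obs = statistic(X[:, labels], X[:, ~labels])
    count = 0
    for _ in range(B):
        perm = rng.permutation(labels)
        if statistic(X[:, perm], X[:, ~perm]) >= obs:
            count += 1
    return (1 + count) / (B + 1)


def _membership_matrix(labels: np.ndarray, B: int,
                       rng: np.random.Generator) -> np.ndarray:
    M = np.empty((B + 1, labels.size), dtype=bool)
    M[0] = labels
    for b in range(1, B + 1):
        M[b] = rng.permutation(labels)
    return M


def _stacked_statistics(X: np.ndarray, M: np.ndarray, n1: int, n2: int,
                        blocks: Sequence[tuple[np.ndarray, int]],
                        ridge_lambda: float) -> tuple[np.ndarray, np.ndarray]:
    """T² and Λ for every relabeling row of the membership matrix ``M``.

    All per-block covariance algebra is stacked across the B+1
    relabelings so the permutation loop runs inside LAPACK.
    """
    n = X.shape[1]
    Mf = M.astype(float)
    t2 = np.zeros(M.shape[0])
    lam = np.zeros(M.shape[0])
    coef = n1 * n2 / n
    for idx, sign in blocks:
        Xb = X[idx]
        k = len(idx)
        R = Xb @ Xb.T                         # total raw scatter, k×k
        R1 = np.einsum("bn,pn,qn->bpq", Mf, Xb, Xb, optimize=True)
        sum1 = Xb @ Mf.T                      # k×(B+1)
        mean1 = sum1 / n1
        mean2 = (Xb.sum(axis=1)[:, None] - sum1) / n2
        m1outer = np.einsum("kb,lb->bkl", mean1, mean1)
        m2outer = np.einsum("kb,lb->bkl", mean2, mean2)
        S1 = R1 / n1 - m1outer
        S2 = (R[None, :, :] - R1) / n2 - m2outer
        Sp = (n1 * S1 + n2 * S2) / n
        if ridge_lambda > 0:
            eye = np.eye(k)
            for S in (S1, S2, Sp):
                diag_mean = np.einsum("bkk->b", S) / k
                S += ridge_lambda * diag_mean[:, None, None] * eye
        d = (mean1 - mean2).T                 # (B+1)×k
        try:
            sol = np.linalg.solve(Sp, d[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise SingularMarginalError(
                "singular pooled clique marginal; enable ridge "
                "regularization (ridge_lambda > 0)") from exc
        t2 += sign * coef * np.einsum("bk,bk->b", d, sol)
        lds = []
        for S, w in ((Sp, n), (S1, -n1), (S2, -n2)):
            s, ld = np.linalg.slogdet(S)
            if np.any(s <= 0):
                raise SingularMarginalError(
                    "singular group clique marginal; enable ridge "
                    "regularization (ridge_lambda > 0)")
            lds.append(w * ld)
        lam += sign * (lds[0] + lds[1] + lds[2])
    return t2, lam


@dataclass
class PermutationTestResult:
    stat_mean: float
    stat_var: float
    p_mean: float
    p_var: float
    B: int


def joint_permutation_test(X: np.ndarray, labels: np.ndarray,
                           blocks: Sequence[tuple[np.ndarray, int]],
                           B: int, rng: np.random.Generator,
                           ridge_lambda: float = 0.0,
                           membership: Optional[np.ndarray] = None
                           ) -> PermutationTestResult:
    """Permutation test of T² and Λ over a shared set of relabelings.

    ``membership`` may supply a precomputed (B+1) × n boolean matrix whose
    first row is the observed labelling, letting several tests (e.g. all
    cliques of one pathway) reuse the same permutations.
    """
    n1 = int(labels.sum())
    n2 = labels.size - n1
    if min(n1, n2) < 3:
        raise ValueError("each group needs at least 3 samples")
    M = membership if membership is not None else \
        _membership_matrix(labels, B, rng)
    t2, lam = _stacked_statistics(X, M, n1, n2, blocks, ridge_lambda)
    if ridge_lambda == 0:
        # T^2 and the LRT are non-negative by theory at lambda = 0; clamp
        # the ~1e-15 cancellation noise so ties at zero count as ties
        t2 = np.maximum(t2, 0.0)
        lam = np.maximum(lam, 0.0)
    p_mean = (1 + int(np.sum(t2[1:] >= t2[0]))) / (M.shape[0])
    p_var = (1 + int(np.sum(lam[1:] >= lam[0]))) / (M.shape[0])
    return PermutationTestResult(float(t2[0]), float(lam[0]),
                                 p_mean, p_var, M.shape[0] - 1)


# ---------------------------------------------------------------------------
# Pathway-level testing
# ---------------------------------------------------------------------------

@dataclass
class PathwayTestResult:
    pathway_id: str
    n_nodes: int
    n_genes: int
    n_mirnas: int
    stat_mean: float
    p_mean: float
    stat_var: float
    p_var: float
    q_mean: float = float("nan")
    q_var: float = float("nan")


def restrict_to_measured(graph: PathwayGraph,
                         expr: ExpressionDataset) -> PathwayGraph:
    """Induced subgraph on the features present in the expression matrix."""
    measured = set(graph.nodes) & set(expr.features)
    dropped = len(graph.nodes) - len(measured)
    if dropped:
        logger.info("pathway %s: %d unmeasured nodes dropped",
                    graph.pathway_id, dropped)
    return graph.subgraph_on(measured)


def needs_ridge(decomp: ChordalDecomposition, n1: int, n2: int) -> bool:
    """Ridge is required when the smaller group is not larger than the widest clique."""
    return min(n1, n2) <= decomp.max_clique_size


def test_pathway(graph: PathwayGraph, expr: ExpressionDataset,
                 config: Config, rng: np.random.Generator
                 ) -> Optional[PathwayTestResult]:
    """Two-group permutation tests (means and covariances) for one pathway.

    The graph is first restricted to measured features (gene and miRNA
    rows live in one concatenated matrix: the statistics are scale-free
    through the concentration matrix, so layers with different
    measurement scales can be mixed).  Returns ``None`` (with a warning)
    when fewer than 2 features are measured.
    """
    sub = restrict_to_measured(graph, expr)
    if len(sub) < 2:
        logger.warning("pathway %s skipped: <2 measured features",
                       graph.pathway_id)
        return None
    decomp = decompose(sub)
    X = expr.matrix(decomp.nodes)
    labels = expr.group_mask()
    n1, n2 = int(labels.sum()), int((~labels).sum())
    ridge = config.ridge_lambda if needs_ridge(decomp, n1, n2) else 0.0
    res = joint_permutation_test(X, labels, decomp.blocks(),
                                 config.permutations, rng, ridge)
    return PathwayTestResult(
        pathway_id=graph.pathway_id, n_nodes=len(sub),
        n_genes=len(sub.genes), n_mirnas=len(sub.mirnas),
        stat_mean=res.stat_mean, p_mean=res.p_mean,
        stat_var=res.stat_var, p_var=res.p_var)


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def results_table(results: Sequence[PathwayTestResult],
                  config: Config) -> pd.DataFrame:
    """Assemble per-pathway results, BH-adjusting each test family separately."""
    results = sorted(results, key=lambda r: r.pathway_id)
    q_mean = adjust_bh([r.p_mean for r in results])
    q_var = adjust_bh([r.p_var for r in results])
    rows = []
    for r, qm, qv in zip(results, q_mean, q_var):
        r.q_mean, r.q_var = float(qm), float(qv)
        selected = _is_selected(r.q_mean, r.q_var, config)
        rows.append({"pathway_id": r.pathway_id, "n_nodes": r.n_nodes,
                     "n_genes": r.n_genes, "n_mirnas": r.n_mirnas,
                     "stat_mean": r.stat_mean, "p_mean": r.p_mean,
                     "q_mean": r.q_mean, "stat_var": r.stat_var,
                     "p_var": r.p_var, "q_var": r.q_var,
                     "selected": selected})
    return pd.DataFrame(rows, columns=["pathway_id", "n_nodes", "n_genes",
                                       "n_mirnas", "stat_mean", "p_mean",
                                       "q_mean", "stat_var", "p_var",
                                       "q_var", "selected"])


def _is_selected(q_mean: float, q_var: float, config: Config) -> bool:
    a = config.alpha_pathway
    if config.selection_mode == "both":
        return bool(q_mean <= a and q_var <= a)
    return bool(q_mean <= a or q_var <= a)


def select_pathways(table: pd.DataFrame, alpha_pathway: float,
                    mode: str = "both") -> list[str]:
    """Pathway ids whose BH-adjusted mean/variance q-values pass ``alpha``.

    Under the default ``both`` rule a pathway needs ``q_mean ≤ α`` and
    ``q_var ≤ α``; ``either`` accepts one passing family.
    """
    if table.empty:
        return []
    if mode == "both":
        keep = (table["q_mean"] <= alpha_pathway) & \
               (table["q_var"] <= alpha_pathway)
    elif mode == "either":
        keep = (table["q_mean"] <= alpha_pathway) | \
               (table["q_var"] <= alpha_pathway)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return sorted(table.loc[keep, "pathway_id"])
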