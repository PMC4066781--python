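"""Simulation generators with known ground truth for every pipeline stage.

The generator draws Gaussian expression data that is Markov to the moralized
pathway graph — exactly the model class the test engine assumes — so planted
signals are recoverable in principle and recovery tests are meaningful.
Group differences are planted on the nodes of a chosen junction-tree path
as a mean shift δ (in group-1 standard deviation units) together with a
covariance difference: a multiplicative perturbation of the
concentration-matrix weights along the path (``cov_perturbation``) and a
marginal variance inflation of the planted nodes in group 2
(``variance_scale``).  The variance component carries most of the
covariance-test signal at realistic sample sizes; edge-weight changes of
plausible magnitude are nearly invisible to any covariance test at n of a
few dozen per group.  A null study is obtained with ``planted_path=None``.  The miRNA layer couples each simulated miRNA to the mean of its
target genes with coefficient c plus independent Gaussian noise; c = 0 gives
null decoys for filter specificity checks, and for a single target the
population correlation is ``c·σ_g / sqrt(c²·σ_g² + σ_ε²)``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph_model import (GENE, ExpressionDataset, PathwayGraph,
                          write_graph)
from .ggm_testing import decompose, moralize

logger = logging.getLogger(__name__)


@dataclass
class MirnaSpec:
    """One simulated miRNA: its targets, coupling c and noise sd σ_ε."""

    targets: tuple[str, ...]
    coupling: float = 1.0
    noise_sd: float = 1.0


@dataclass
class SimulationSpec:
    """Ground-truth description of one simulated two-group study.

    Defaults describe the standard benchmark regime: a 20-gene connected
    sparse random DAG (extra-edge density 0.08, giving signalling-cascade
    connectivity), 40 samples per group, and a planted two-clique
    junction-tree chain carrying a mean shift of δ = 1.5 baseline
    standard deviations together with a three-fold group-2 variance
    inflation — a strongly dysregulated local circuit, sized by power
    analysis so that each test family is individually detectable at the
    benchmark sample size.  ``planted_path=None`` gives a null study with
    both groups identically distributed.
    """

    n_genes: int = 20
    density: float = 0.08
    n1: int = 40
    n2: int = 40
    delta: float = 1.5
    planted_path: Optional[Sequence[str] | str] = "auto"
    planted_cliques: int = 2  # junction-tree cliques spanned by "auto"
    cov_perturbation: float = 1.0
    variance_scale: float = 3.0
    mirnas: Optional[dict[str, MirnaSpec]] = None
    edge_weight_range: tuple[float, float] = (0.25, 0.35)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0,1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _rng_for(spec: SimulationSpec, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(spec.seed)
    streams = {"graph": 0, "expression": 1, "mirna": 2}
    return np.random.default_rng(ss.spawn(3)[streams[stream]])


def gene_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_pathway(spec: SimulationSpec) -> PathwayGraph:
    """Random connected DAG over ``n_genes`` gene nodes.

    Nodes get a random topological order; every non-root draws exactly
    one parent uniformly among its predecessors (guaranteeing weak
    connectivity), and each remaining earlier→later pair becomes an
    extra edge independently with probability ``density``.
    """
    rng = _rng_for(spec, "graph")
    names = gene_names(spec.n_genes)
    order = [str(n) for n in rng.permutation(names)]
    graph = PathwayGraph(f"sim{spec.seed}")
    for name in names:
        graph.add_node(name, GENE)
    forced: set[tuple[str, str]] = set()
    for i in range(1, len(order)):
        parent = order[int(rng.integers(0, i))]
        graph.add_edge(parent, order[i], "simulated")
        forced.add((parent, order[i]))
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            pair = (order[i], order[j])
            if pair in forced:
                continue
            if rng.random() < spec.density:
                graph.add_edge(*pair, "simulated")
    return graph


def resolve_planted_path(graph: PathwayGraph,
                         spec: SimulationSpec) -> tuple[str, ...]:
    """Planted node set: explicit list, or an automatic junction-tree chain.

    ``auto`` picks the lexicographically smallest junction-tree path of
    maximal length, truncated to ``planted_cliques`` cliques, and plants
    on the union of those cliques' nodes — so the planted signal respects
    the clique structure the analysis will see.
    """
    if spec.planted_path is None:
        return ()
    if spec.planted_path != "auto":
        missing = [n for n in spec.planted_path if n not in graph]
        if missing:
            raise ValueError(f"planted nodes not in graph: {missing}")
        return tuple(spec.planted_path)
    decomp = decompose(graph)
    jt = decomp.junction_tree
    cliques = jt.cliques
    best = (cliques[0],)
    for c1, c2 in itertools.combinations(cliques, 2):
        if not nx.has_path(jt.tree, c1, c2):
            continue
        path = tuple(nx.shortest_path(jt.tree, c1, c2))
        # longest chain wins; ties resolve to the lexicographically
        # smallest clique sequence for determinism
        if len(path) > len(best) or (len(path) == len(best) and path < best):
            best = path
    chain = best[:spec.planted_cliques]
    nodes: list[str] = []
    for clique in chain:
        for n in clique:
            if n not in nodes:
                nodes.append(n)
    return tuple(nodes)


def _precision_matrix(graph: PathwayGraph, spec: SimulationSpec,
                      rng: np.random.Generator,
                      planted: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Unit-diagonal precision matrices (K, K′) Markov to the moral graph.

    Moral-edge weights are drawn from ``edge_weight_range`` (negative,
    i.e. positive partial correlations); K′ multiplies the weights of
    planted-path edges by ``cov_perturbation``.  Off-diagonals are
    rescaled toward diagonal dominance whenever positive definiteness
    would fail.
    """
    moral = moralize(graph)
    nodes = sorted(moral.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    p = len(nodes)
    lo, hi = spec.edge_weight_range
    K = np.eye(p)
    planted_set = set(planted)
    perturbed: list[tuple[int, int]] = []
    for u, v in sorted(moral.edges):
        w = -rng.uniform(lo, hi)
        K[index[u], index[v]] = K[index[v], index[u]] = w
        if u in planted_set and v in planted_set:
            perturbed.append((index[u], index[v]))
    K = _ensure_dominant(K)
    K2 = K.copy()
    for i, j in perturbed:
        K2[i, j] = K2[j, i] = K[i, j] * spec.cov_perturbation
    K2 = _ensure_dominant(K2)
    return K, K2


def _ensure_dominant(K: np.ndarray) -> np.ndarray:
    """Rescale off-diagonals so every row is strictly diagonally dominant."""
    off = K - np.diag(np.diag(K))
    row = np.abs(off).sum(axis=1).max()
    if row > 0.95:
        scale = 0.95 / row
        logger.info("precision matrix rescaled by %.3f for positive "
                    "definiteness", scale)
        K = np.diag(np.diag(K)) + off * scale
    return K


def simulate_expression(graph: PathwayGraph, spec: SimulationSpec,
                        return_covariances: bool = False):
    """Two-group Gaussian expression Markov to the moralized pathway.

    Group 1 (label ``g1``) ~ N(0, K⁻¹); group 2 (``g2``) ~ N(μ, Σ₂) with
    Σ₂ = D K′⁻¹ D, where K′ carries the planted edge perturbation, D
    inflates planted-node standard deviations by sqrt(``variance_scale``)
    and μ carries δ baseline standard deviations on the planted nodes.
    Returns the dataset (and optionally the true per-group covariance
    matrices keyed by node order).
    """
    rng = _rng_for(spec, "expression")
    planted = resolve_planted_path(graph, spec)
    K, K2 = _precision_matrix(graph, spec, rng, planted)
    nodes = sorted(graph.nodes)
    sigma1 = np.linalg.inv(K)
    sigma2 = np.linalg.inv(K2)
    # planted covariance difference: marginal variance inflation of the
    # planted nodes in group 2 (congruence transform keeps Σ₂ PD)
    if planted and spec.variance_scale != 1.0:
        scale = np.ones(len(nodes))
        for i, n in enumerate(nodes):
            if n in planted:
                scale[i] = math.sqrt(spec.variance_scale)
        sigma2 = sigma2 * np.outer(scale, scale)
    mu = np.zeros(len(nodes))
    for i, n in enumerate(nodes):
        if n in planted:
            mu[i] = spec.delta * math.sqrt(sigma1[i, i])
    L1 = np.linalg.cholesky(sigma1)
    L2 = np.linalg.cholesky(sigma2)
    X1 = L1 @ rng.standard_normal((len(nodes), spec.n1))
    X2 = mu[:, None] + L2 @ rng.standard_normal((len(nodes), spec.n2))
    samples = [f"S{i:03d}" for i in range(1, spec.n1 + spec.n2 + 1)]
    values = pd.DataFrame(np.hstack([X1, X2]), index=nodes, columns=samples)
    groups = pd.Series(["g1"] * spec.n1 + ["g2"] * spec.n2, index=samples)
    ds = ExpressionDataset(values, groups)
    if return_covariances:
        return ds, {"nodes": nodes, "sigma1": sigma1, "sigma2": sigma2,
                    "planted": planted}
    return ds


def default_mirna_layer(planted: Sequence[str],
                        genes: Sequence[str]) -> dict[str, MirnaSpec]:
    """Standard four-miRNA layer: two coupled regulators of planted genes
    plus two pure-noise decoys."""
    anchor = list(planted) if planted else list(genes)
    t1 = tuple(anchor[: min(2, len(anchor))])
    t2 = tuple(anchor[-min(2, len(anchor)):])
    return {
        "miR-01": MirnaSpec(targets=t1, coupling=1.0, noise_sd=1.0),
        "miR-02": MirnaSpec(targets=t2, coupling=-1.0, noise_sd=1.0),
        "miR-03": MirnaSpec(targets=t1[:1], coupling=0.0, noise_sd=1.0),
        "miR-04": MirnaSpec(targets=t2[-1:], coupling=0.0, noise_sd=1.0),
    }


def noise_sd_for_r(target_sd: float, r: float, coupling: float = 1.0) -> float:
    """σ_ε giving population correlation ``r`` with a single target.

    Inverts ``r = c·σ_g / sqrt(c²σ_g² + σ_ε²)``.
    """
    if not (0 < abs(r) < 1):
        raise ValueError("r must lie strictly between 0 and 1 in magnitude")
    return abs(coupling) * target_sd * math.sqrt(1.0 / r**2 - 1.0)


def simulate_mirna_layer(gene_expr: ExpressionDataset, spec: SimulationSpec,
                         mirnas: Optional[dict[str, MirnaSpec]] = None,
                         true_cov: Optional[dict] = None
                         ) -> tuple[ExpressionDataset, pd.DataFrame]:
    """miRNA expression coupled to target-gene means, plus its truth table.

    Each miRNA value is ``c · mean(target values) + ε`` with
    ε ~ N(0, σ_ε²).  The truth table lists every (mirna, target) pair
    with its coupling, noise sd and population correlation (computed from
    the true gene covariance when available, otherwise from the sample).
    """
    rng = _rng_for(spec, "mirna")
    if mirnas is None:
        mirnas = spec.mirnas
    if mirnas is None:
        planted = resolve_planted_path(
            simulate_pathway(spec), spec) if spec.planted_path else ()
        mirnas = default_mirna_layer(planted, gene_expr.features)
    n = gene_expr.n_samples
    rows = {}
    truth = []
    if true_cov is not None:
        cov = np.asarray(true_cov["sigma1"])
        cov_nodes = {nd: i for i, nd in enumerate(true_cov["nodes"])}
    else:
        sample_cov = np.cov(gene_expr.values.to_numpy())
        cov = np.atleast_2d(sample_cov)
        cov_nodes = {nd: i for i, nd in enumerate(gene_expr.features)}
    for name in sorted(mirnas):
        ms = mirnas[name]
        missing = [t for t in ms.targets if t not in gene_expr.values.index]
        if missing:
            raise ValueError(f"miRNA {name}: targets not in gene data: "
                             f"{missing}")
        target_mean = gene_expr.values.loc[list(ms.targets)].mean(axis=0)
        eps = ms.noise_sd * rng.standard_normal(n)
        rows[name] = ms.coupling * target_mean.to_numpy() + eps
        idx = [cov_nodes[t] for t in ms.targets]
        k = len(idx)
        var_mean = float(cov[np.ix_(idx, idx)].mean())
        var_m = ms.coupling**2 * var_mean + ms.noise_sd**2
        for t in ms.targets:
            j = cov_nodes[t]
            cov_mt = ms.coupling * float(cov[idx, j].mean())
            denom = math.sqrt(max(var_m, 1e-300) * cov[j, j])
            truth.append({"mirna": name, "target": t,
                          "coupling": ms.coupling,
                          "noise_sd": ms.noise_sd,
                          "population_r": cov_mt / denom if denom else 0.0})
    values = pd.DataFrame(rows, index=gene_expr.samples).T
    values = values.loc[sorted(rows)]
    ds = ExpressionDataset(values)
    ds.groups = gene_expr.groups
    truth_df = pd.DataFrame(truth, columns=["mirna", "target", "coupling",
                                            "noise_sd", "population_r"])
    return ds, truth_df


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

BUNDLE_FILES = ("pathway.sif", "pathway_nodes.tsv", "gene_expr.tsv",
                "mirna_expr.tsv", "groups.tsv", "validated.tsv",
                "predicted.tsv", "truth.tsv")


def write_fixture_bundle(spec: SimulationSpec, out_dir) -> dict[str, Path]:
    """Write a complete, self-contained input set for the CLI.

    Files: pathway SIF + node attributes, gene and miRNA expression TSVs,
    groups TSV, validated and predicted interaction tables and a truth
    manifest (planted nodes + true interactions).  Coupled miRNAs split
    between the validated table and the predicted table (P_ct 0.9); the
    decoys go to the predicted table with P_ct 0.85 (passes the P_ct
    filter, should fail the correlation screen) and 0.5 (fails P_ct).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = simulate_pathway(spec)
    planted = resolve_planted_path(graph, spec)
    gene_expr, cov = simulate_expression(graph, spec, return_covariances=True)
    mirnas = spec.mirnas or default_mirna_layer(planted, gene_expr.features)
    mirna_expr, truth = simulate_mirna_layer(gene_expr, spec, mirnas,
                                             true_cov=cov)

    paths = {name: out / name for name in BUNDLE_FILES}
    write_graph(graph, paths["pathway.sif"], paths["pathway_nodes.tsv"])
    gene_expr.to_tsv(paths["gene_expr.tsv"])
    mirna_expr.to_tsv(paths["mirna_expr.tsv"])
    with open(paths["groups.tsv"], "w", encoding="utf-8") as fh:
        for s in gene_expr.samples:
            fh.write(f"{s}\t{gene_expr.groups[s]}\n")

    names = sorted(mirnas)
    coupled = [m for m in names if mirnas[m].coupling != 0]
    decoys = [m for m in names if mirnas[m].coupling == 0]
    validated = coupled[::2]
    predicted = coupled[1::2]
    with open(paths["validated.tsv"], "w", encoding="utf-8") as fh:
        fh.write("mirna\ttarget\n")
        for m in validated:
            for t in mirnas[m].targets:
                fh.write(f"{m}\t{t}\n")
    with open(paths["predicted.tsv"], "w", encoding="utf-8") as fh:
        fh.write("mirna\ttarget\tpct\n")
        for m in predicted:
            for t in mirnas[m].targets:
                fh.write(f"{m}\t{t}\t0.9\n")
        for i, m in enumerate(decoys):
            pct = 0.85 if i % 2 == 0 else 0.5
            for t in mirnas[m].targets:
                fh.write(f"{m}\t{t}\t{pct}\n")

    manifest = [{"record_type": "planted_node", "mirna": "", "target": n,
                 "coupling": "", "noise_sd": "", "population_r": ""}
                for n in planted]
    for _, row in truth.iterrows():
        manifest.append({"record_type": "interaction",
                         "mirna": row["mirna"], "target": row["target"],
                         "coupling": row["coupling"],
                         "noise_sd": row["noise_sd"],
                         "population_r": row["population_r"]})
    pd.DataFrame(manifest).to_csv(paths["truth.tsv"], sep="\t", index=False,
                                  float_format="%.6g")
    return paths


def read_truth(path) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Read a bundle's truth manifest: (planted nodes, interaction table)."""
    df = pd.read_csv(path, sep="\t", dtype={"record_type": str,
                                            "mirna": str, "target": str})
    planted = tuple(df.loc[df["record_type"] == "planted_node", "target"])
    inter = df[df["record_type"] == "interaction"].copy()
    return planted, inter
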