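"""Core graph and dataset types plus readers/writers for the pipeline's file formats.

The pipeline works on three kinds of objects:

* :class:`PathwayGraph` — a typed (gene / miRNA) directed graph with per-edge
  relation labels and provenance, read from and written to SIF-style TSV.
* :class:`ExpressionDataset` — a feature × sample expression matrix with a
  two-group sample annotation, shared by the mRNA and miRNA layers.
* :class:`InteractionRecord` — one miRNA→target interaction carrying its
  evidence class and, for predictions, the TargetScan P_ct score and the
  Pearson r / BH q attached by correlation filtering.

File dialects (all plain TSV, UTF-8, decimal point):

* SIF: ``source<TAB>relation<TAB>target``, one edge per line, no header.
* Expression: header ``feature<TAB>sample1<TAB>...``, numeric body.
* Groups: ``sample<TAB>group``, no header, exactly two distinct labels.
* Interactions: header ``mirna<TAB>target[<TAB>pct]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
MIRNA = "miRNA"
NODE_TYPES = (GENE, MIRNA)

#: Edge / interaction provenance classes.
PROVENANCE = ("pathway", "validated", "predicted", "both")


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _merge_evidence(a: str, b: str) -> str:
    if a == b:
        return a
    if {a, b} <= {"validated", "predicted", "both"}:
        return "both"
    # pathway provenance never mixes with miRNA evidence classes
    raise ValueError(f"cannot merge provenance {a!r} with {b!r}")


class PathwayGraph:
    """Directed pathway graph with gene/miRNA typed nodes.

    Edges are identified by the triple ``(source, target, relation)``;
    parallel edges with distinct relation labels are kept as distinct
    triples but collapse to a single adjacency for analysis
    (:meth:`skeleton`).  miRNA nodes may only regulate: they have no
    incoming edges and at least one outgoing edge to a gene.
    """

    def __init__(self, pathway_id: str):
        self.pathway_id = str(pathway_id)
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------
    def add_node(self, node: str, node_type: str = GENE, **attrs) -> None:
        if not node:
            raise ValueError("empty node identifier")
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        if node in self._g and self._g.nodes[node]["node_type"] != node_type:
            raise ValueError(f"node {node!r} re-declared with a different type")
        self._g.add_node(node, node_type=node_type, **attrs)

    def add_edge(self, source: str, target: str, relation: str,
                 provenance: str = "pathway") -> None:
        """Add the edge triple, creating missing endpoints as gene nodes.

        Self-loops are rejected; a duplicate triple is merged (miRNA
        evidence classes combine to ``both``).
        """
        if source == target:
            raise ValueError(f"self-loop on {source!r}")
        if provenance not in PROVENANCE:
            raise ValueError(f"unknown provenance {provenance!r}")
        for n in (source, target):
            if n not in self._g:
                self.add_node(n, GENE)
        data = self._g.get_edge_data(source, target)
        if data is None:
            self._g.add_edge(source, target, relations={relation: provenance})
        else:
            rel = data["relations"]
            rel[relation] = (provenance if relation not in rel
                             else _merge_evidence(rel[relation], provenance))

    # -- inspection ---------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def node_type(self, node: str) -> str:
        return self._g.nodes[node]["node_type"]

    def node_attrs(self, node: str) -> dict:
        return dict(self._g.nodes[node])

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self._g.nodes(data=True)
                      if d["node_type"] == GENE)

    @property
    def mirnas(self) -> list[str]:
        return sorted(n for n, d in self._g.nodes(data=True)
                      if d["node_type"] == MIRNA)

    def edges(self) -> Iterator[tuple[str, str, str, str]]:
        """Yield ``(source, target, relation, provenance)`` triples, sorted."""
        out = []
        for u, v, d in self._g.edges(data=True):
            for rel, prov in d["relations"].items():
                out.append((u, v, rel, prov))
        out.sort()
        return iter(out)

    def edge_provenance(self, source: str, target: str) -> Optional[dict]:
        d = self._g.get_edge_data(source, target)
        return dict(d["relations"]) if d else None

    @property
    def n_edges(self) -> int:
        return sum(len(d["relations"]) for _, _, d in self._g.edges(data=True))

    def edge_counts(self) -> dict[str, int]:
        """Counts of miRNA→gene and gene→gene edge triples."""
        mg = gg = 0
        for u, v, rel, prov in self.edges():
            if self.node_type(u) == MIRNA:
                mg += 1
            else:
                gg += 1
        return {"mirna_gene": mg, "gene_gene": gg}

    def has_node(self, node: str) -> bool:
        return node in self._g

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    # -- views --------------------------------------------------------
    def directed(self) -> nx.DiGraph:
        """Adjacency-collapsed directed view (one edge per node pair)."""
        g = nx.DiGraph()
        g.add_nodes_from(self._g.nodes(data=True))
        g.add_edges_from(self._g.edges())
        return g

    def skeleton(self) -> nx.Graph:
        """Undirected adjacency skeleton used by the GGM machinery."""
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from(self._g.edges())
        return g

    def subgraph_on(self, nodes: Iterable[str]) -> "PathwayGraph":
        """Induced subgraph on ``nodes`` (unknown ids ignored)."""
        keep = set(nodes) & set(self._g.nodes)
        sub = PathwayGraph(self.pathway_id)
        for n in sorted(keep):
            sub.add_node(n, self.node_type(n))
        for u, v, rel, prov in self.edges():
            if u in keep and v in keep:
                sub.add_edge(u, v, rel, prov)
        return sub

    def copy(self) -> "PathwayGraph":
        g = PathwayGraph(self.pathway_id)
        g._g = self._g.copy()
        return g

    # -- invariants ---------------------------------------------------
    def validate(self, require_mirna_regulation: bool = True) -> None:
        """Check structural invariants, raising ``ValueError`` on violation.

        ``require_mirna_regulation`` enforces that every miRNA node has
        in-degree 0 and at least one outgoing edge to a gene; it is
        relaxed for meta-pathway graphs whose induced subgraphs may
        strand a miRNA.
        """
        for n in self._g.nodes:
            if not n:
                raise ValueError("empty node identifier")
        for u, v in self._g.edges():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
        for m in self.mirnas:
            if self._g.in_degree(m) > 0:
                raise ValueError(f"miRNA node {m!r} has incoming edges")
            if require_mirna_regulation:
                targets = [t for t in self._g.successors(m)
                           if self.node_type(t) == GENE]
                if not targets:
                    raise ValueError(f"miRNA node {m!r} regulates no gene")

    def is_isomorphic_to(self, other: "PathwayGraph") -> bool:
        """Identity-based equality of typed nodes and edge triples."""
        if set(self.nodes) != set(other.nodes):
            return False
        if any(self.node_type(n) != other.node_type(n) for n in self.nodes):
            return False
        mine = {(u, v, r) for u, v, r, _ in self.edges()}
        theirs = {(u, v, r) for u, v, r, _ in other.edges()}
        return mine == theirs


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

class ExpressionDataset:
    """Feature × sample expression matrix with an optional two-group labelling.

    ``values`` is a :class:`pandas.DataFrame` (index = features, columns =
    samples).  ``groups`` maps every sample to one of exactly two labels;
    group order is the lexicographic label order, so ``n1`` counts the
    lexicographically smaller label.
    """

    def __init__(self, values: pd.DataFrame,
                 groups: Optional[pd.Series] = None):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        numeric = values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna().any(axis=1)
        if bad.any():
            raise ParseError(
                f"feature {numeric.index[bad][0]!r} has missing or "
                "non-numeric values")
        self.values = numeric.astype(float)
        self.groups: Optional[pd.Series] = None
        if groups is not None:
            self._attach_groups(groups)

    def _attach_groups(self, groups: pd.Series) -> None:
        groups = groups.astype(str)
        missing = [s for s in self.values.columns if s not in groups.index]
        if missing:
            raise ParseError(f"sample {missing[0]!r} has no group label")
        groups = groups.loc[list(self.values.columns)]
        labels = sorted(groups.unique())
        if len(labels) != 2:
            raise ParseError(
                f"expected exactly 2 group labels, found {len(labels)}: "
                f"{labels}")
        self.groups = groups

    # -- basic views --------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_labels(self) -> tuple[str, str]:
        if self.groups is None:
            raise ValueError("no groups attached")
        labels = sorted(self.groups.unique())
        return labels[0], labels[1]

    @property
    def group_sizes(self) -> tuple[int, int]:
        a, b = self.group_labels
        return int((self.groups == a).sum()), int((self.groups == b).sum())

    def group_mask(self) -> np.ndarray:
        """Boolean mask over samples: True for the first (lexicographic) group."""
        a, _ = self.group_labels
        return (self.groups == a).to_numpy()

    def matrix(self, feature_order: Sequence[str]) -> np.ndarray:
        """Dense matrix (len(feature_order) × n_samples) in the given row order."""
        missing = [f for f in feature_order if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in dataset: {missing[:5]}")
        return self.values.loc[list(feature_order)].to_numpy()

    def subset(self, feature_order: Sequence[str]) -> "ExpressionDataset":
        ds = ExpressionDataset(self.values.loc[list(feature_order)].copy())
        ds.groups = self.groups
        return ds

    def concat_rows(self, other: "ExpressionDataset") -> "ExpressionDataset":
        """Stack two datasets measured on the same samples (e.g. genes + miRNAs)."""
        if set(self.samples) != set(other.samples):
            raise ValueError("sample sets differ between datasets")
        shared = set(self.features) & set(other.features)
        if shared:
            raise ValueError(f"duplicate features across layers: "
                             f"{sorted(shared)[:5]}")
        aligned = other.values.loc[:, list(self.values.columns)]
        ds = ExpressionDataset(pd.concat([self.values, aligned]))
        ds.groups = self.groups
        return ds

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

@dataclass
class InteractionRecord:
    """One miRNA→target interaction with its evidence and filter statistics."""

    mirna: str
    target: str
    evidence: str  # validated | predicted | both
    pct: Optional[float] = None
    r: Optional[float] = None
    q: Optional[float] = None

    def __post_init__(self):
        if self.evidence not in ("validated", "predicted", "both"):
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.pct is not None and not (0.0 <= self.pct <= 1.0):
            raise ValueError(f"pct out of [0,1]: {self.pct}")
        if self.r is not None and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"r out of [-1,1]: {self.r}")
        if self.q is not None and not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q out of [0,1]: {self.q}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna, self.target)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Pipeline thresholds and run parameters.

    Defaults: TargetScan P_ct ≥ 0.8,
    correlation filter |r| ≥ 0.4 with BH q ≤ 0.05, pathway selection at
    BH-adjusted ≤ 0.1 for both the mean and the covariance test, clique
    significance at 0.05 and at most one gap per path.
    """

    pct_min: float = 0.8
    r_min: float = 0.4
    q_max_corr: float = 0.05
    alpha_pathway: float = 0.1
    alpha_clique: float = 0.05
    max_gaps: int = 1
    gap_penalty: Optional[float] = None  # defaults to -log10(alpha_clique)
    permutations: int = 1000
    seed: int = 0
    ridge_lambda: float = 1e-3
    clique_mode: str = "either"  # mean | variance | either
    selection_mode: str = "both"  # both | either

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, lo, hi in (("pct_min", 0, 1), ("r_min", 0, 1),
                             ("q_max_corr", 0, 1), ("alpha_pathway", 0, 1),
                             ("alpha_clique", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")
        if self.max_gaps < 0:
            raise ValueError(f"max_gaps={self.max_gaps} must be >= 0")
        if self.permutations < 1:
            raise ValueError(f"permutations={self.permutations} must be >= 1")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.clique_mode not in ("mean", "variance", "either"):
            raise ValueError(f"unknown clique_mode {self.clique_mode!r}")
        if self.selection_mode not in ("both", "either"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    @property
    def effective_gap_penalty(self) -> float:
        if self.gap_penalty is not None:
            return self.gap_penalty
        return -math.log10(self.alpha_clique)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "Config":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown config key {unknown[0]!r}")
        return cls(**dict(mapping))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_pathway_sif(path, pathway_id: str) -> PathwayGraph:
    """Read a gene-only pathway from a 3-column SIF TSV.

    Duplicate edge lines collapse; self-loops are dropped with a logged
    warning; a malformed or empty file raises :class:`ParseError`.
    """
    graph = PathwayGraph(pathway_id)
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated "
                    f"columns, got {len(parts)}")
            src, rel, dst = parts
            n_lines += 1
            if src == dst:
                logger.warning("%s: line %d: dropping self-loop on %r",
                               path, lineno, src)
                graph.add_node(src, GENE)
                continue
            graph.add_edge(src, dst, rel, provenance="pathway")
    if n_lines == 0:
        raise ParseError(f"{path}: empty pathway file")
    return graph


def read_wired_sif(sif_path, node_attr_path, pathway_id: str) -> PathwayGraph:
    """Read a wired pathway: SIF edges plus a node/type/provenance TSV.

    The evidence class of individual miRNA edges is not serialized in
    this format; re-read miRNA edges carry provenance ``validated``.
    """
    attrs = pd.read_csv(node_attr_path, sep="\t", dtype=str)
    required = {"node", "type"}
    if not required <= set(attrs.columns):
        raise ParseError(f"{node_attr_path}: missing columns "
                         f"{sorted(required - set(attrs.columns))}")
    graph = PathwayGraph(pathway_id)
    for _, row in attrs.iterrows():
        if row["type"] not in NODE_TYPES:
            raise ParseError(f"{node_attr_path}: unknown node type "
                             f"{row['type']!r}")
        graph.add_node(row["node"], row["type"])
    with open(sif_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{sif_path}: line {lineno}: expected 3 "
                                 f"columns, got {len(parts)}")
            src, rel, dst = parts
            for n in (src, dst):
                if n not in graph:
                    raise ParseError(f"{sif_path}: line {lineno}: node {n!r} "
                                     f"not declared in {node_attr_path}")
            prov = ("validated" if graph.node_type(src) == MIRNA
                    else "pathway")
            graph.add_edge(src, dst, rel, provenance=prov)
    return graph


def write_graph(graph: PathwayGraph, sif_path, node_attr_path) -> None:
    """Write a pathway as canonical SIF + node-attribute TSV.

    Output ordering is canonical (lexicographic over nodes and edge
    triples), so write→read→write is byte-identical.
    """
    with open(sif_path, "w", encoding="utf-8") as fh:
        for u, v, rel, _ in graph.edges():
            fh.write(f"{u}\t{rel}\t{v}\n")
    with open(node_attr_path, "w", encoding="utf-8") as fh:
        fh.write("node\ttype\tprovenance\n")
        for n in graph.nodes:
            attrs = graph.node_attrs(n)
            prov = attrs.get("source_pathways")
            prov = (",".join(sorted(prov)) if prov else graph.pathway_id)
            fh.write(f"{n}\t{graph.node_type(n)}\t{prov}\n")


def read_expression(path) -> ExpressionDataset:
    """Read a feature × sample expression TSV (no groups attached)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionDataset(df)


def read_groups(path, dataset: ExpressionDataset) -> ExpressionDataset:
    """Attach a 2-column sample→group TSV (no header) to a dataset."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if table.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {table.shape[1]}")
    if table[0].duplicated().any():
        dup = table[0][table[0].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample {dup!r}")
    groups = pd.Series(table[1].to_numpy(), index=table[0].to_numpy())
    ds = ExpressionDataset(dataset.values.copy())
    ds._attach_groups(groups)
    return ds


def read_interactions(path, evidence: str) -> list[InteractionRecord]:
    """Read a miRNA→target interaction TSV.

    ``evidence`` is ``validated`` or ``predicted``; predicted tables must
    carry a ``pct`` column.  Duplicate (mirna, target) rows collapse,
    keeping the maximum pct.
    """
    if evidence not in ("validated", "predicted"):
        raise ValueError(f"evidence must be validated or predicted, "
                         f"got {evidence!r}")
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "target": str})
    for col in ("mirna", "target"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if evidence == "predicted" and "pct" not in df.columns:
        raise ParseError(f"{path}: predicted table missing 'pct' column")
    records: dict[tuple[str, str], InteractionRecord] = {}
    for _, row in df.iterrows():
        key = (row["mirna"], row["target"])
        pct = float(row["pct"]) if evidence == "predicted" else None
        if key in records:
            if pct is not None and pct > records[key].pct:
                records[key].pct = pct
            continue
        records[key] = InteractionRecord(key[0], key[1], evidence, pct=pct)
    return [records[k] for k in sorted(records)]


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    rows = [{"mirna": r.mirna, "target": r.target, "evidence": r.evidence,
             "pct": r.pct, "r": r.r, "q": r.q}
            for r in sorted(records, key=lambda r: r.key)]
    pd.DataFrame(rows, columns=["mirna", "target", "evidence",
                                "pct", "r", "q"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
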