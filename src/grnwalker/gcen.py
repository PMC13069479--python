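"""Gene co-expression network (GCEN) construction.

Raw expression values are variance-stabilised with the inverse hyperbolic
sine, pairwise Pearson correlation is computed between all genes across
cells, and gene pairs whose absolute correlation exceeds a threshold
(default 0.1) become undirected, signed-weight edges.  Negative correlations
are kept as negative weights: repressive co-expression is signal downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "arcsinh_transform",
    "pearson_matrix",
    "build_network",
    "build_gcen",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix with unique identifiers and per-gene TF flags."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_tf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x cells matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.shape[1] < 2:
            raise ValueError("at least 2 cells are required (correlation needs >= 2 observations)")
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = [k for k, n in Counter(ids).items() if n > 1]
            if dup:
                raise ValueError(f"duplicate {label} identifiers: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if self.is_tf is None:
            self.is_tf = np.zeros(len(self.gene_ids), dtype=bool)
        else:
            self.is_tf = np.asarray(self.is_tf, dtype=bool)
            if self.is_tf.shape != (len(self.gene_ids),):
                raise ValueError("is_tf must hold one flag per gene")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def gene_index(self) -> dict[str, int]:
        return self._index

    @property
    def tf_ids(self) -> list[str]:
        return [g for g, f in zip(self.gene_ids, self.is_tf) if f]

    def set_tfs(self, tf_ids: Iterable[str], strict: bool = False) -> None:
        """Flag the listed genes as transcription factors."""
        tfs = set(tf_ids)
        missing = tfs - set(self.gene_ids)
        if missing and strict:
            raise ValueError(f"TF identifiers absent from the matrix: {sorted(missing)}")
        if missing:
            logger.warning("%d TF identifiers not present in the matrix", len(missing))
        self.is_tf = np.array([g in tfs for g in self.gene_ids], dtype=bool)


def arcsinh_transform(values: np.ndarray) -> np.ndarray:
    """Elementwise asinh(x) = ln(x + sqrt(x^2 + 1)); variance stabilisation."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("arcsinh_transform requires finite input")
    return np.arcsinh(values)


def pearson_matrix(expr: "ExpressionMatrix | np.ndarray") -> np.ndarray:
    """Pairwise Pearson correlation between all genes across cells.

    Zero-variance genes have undefined correlation; their rows/columns
    (including the diagonal entry) are set to 0 so that they can never form
    edges.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D genes x cells matrix")
    if values.shape[1] < 2:
        raise ValueError("Pearson correlation requires at least 2 cells")
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    nonconstant = norms > 0
    corr = np.zeros((values.shape[0], values.shape[0]), dtype=float)
    if nonconstant.any():
        unit = centred[nonconstant] / norms[nonconstant, None]
        block = unit @ unit.T
        np.clip(block, -1.0, 1.0, out=block)
        corr[np.ix_(nonconstant, nonconstant)] = block
        idx = np.where(nonconstant)[0]
        corr[idx, idx] = 1.0
    return corr


class CoexpressionNetwork:
    """Undirected weighted gene graph; edge weight is the signed Pearson r.

    Genes with no surviving edge are kept as isolated nodes so that gene
    indexing stays stable; they can never anchor or join subgraphs.
    """

    def __init__(self, gene_ids: Sequence[str], threshold: float):
        self.threshold = float(threshold)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(str(g) for g in gene_ids)

    # -- construction ------------------------------------------------------
    def _add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed in the co-expression network")
        if not abs(weight) > self.threshold:
            raise ValueError("edge weight does not exceed the retention threshold")
        self.graph.add_edge(u, v, weight=float(weight))

    # -- queries -----------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def neighbors(self, gene: str) -> list[str]:
        if gene not in self.graph:
            raise KeyError(f"gene {gene!r} is not in the network")
        return list(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, w in self.graph.edges.data("weight"):
            yield u, v, w

    def induced_edges(self, nodes: Sequence[str]) -> list[tuple[str, str, float]]:
        """All network edges with both endpoints in ``nodes``.

        Canonical order: by position of the endpoints within ``nodes``.
        """
        pos = {g: i for i, g in enumerate(nodes)}
        out: list[tuple[str, str, float]] = []
        for u in nodes:
            for v in self.graph.neighbors(u):
                if v in pos and pos[u] < pos[v]:
                    out.append((u, v, self.graph.edges[u, v]["weight"]))
        out.sort(key=lambda e: (pos[e[0]], pos[e[1]]))
        return out

    # -- io ----------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [(u, v, w) for u, v, w in self.edges()]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def build_network(
    corr: np.ndarray,
    gene_ids: Sequence[str],
    threshold: float = 0.1,
) -> CoexpressionNetwork:
    """Retain gene pairs with ``|corr| > threshold`` (strict) as edges."""
    corr = np.asarray(corr, dtype=float)
    n = len(gene_ids)
    if corr.shape != (n, n):
        raise ValueError("correlation matrix shape does not match gene_ids")
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if np.max(np.abs(corr - corr.T)) > 1e-8:
        raise ValueError("correlation matrix is not symmetric")
    net = CoexpressionNetwork(gene_ids, threshold)
    ii, jj = np.where(np.triu(np.abs(corr), k=1) > threshold)
    for i, j in zip(ii.tolist(), jj.tolist()):
        net._add_edge(gene_ids[i], gene_ids[j], corr[i, j])
    return net


def build_gcen(expr: ExpressionMatrix, threshold: float = 0.1) -> CoexpressionNetwork:
    """Full pipeline: arcsinh transform, Pearson correlation, thresholding."""
    corr = pearson_matrix(arcsinh_transform(expr.values))
    net = build_network(corr, expr.gene_ids, threshold)
    logger.info(
        "built co-expression network: %d genes, %d edges (|r| > %.3g)",
        expr.n_genes,
        net.n_edges,
        threshold,
    )
    return net
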