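"""Ground-truth labelling, balanced negative sampling and feature assembly.

A sampled subgraph becomes a training example only if at least one known
regulatory edge connects two of its nodes; otherwise it is discarded.
Negatives are ordered node pairs drawn uniformly from within the subgraph,
matched 1:1 to the positives, and excluded from the global ground truth so
that unknown-but-true edges never enter as false negatives of record.

Node features are the subgraph's (arcsinh-transformed) expression values,
z-scored per cell across the subgraph's genes, plus one binary TF-identity
channel.  The per-cell normalisation makes recurring genes context-specific
instances and prevents the model from memorising gene identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gcen import ExpressionMatrix, arcsinh_transform
from .walker import TFAnchoredSubgraph

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthNetwork",
    "LabeledSubgraph",
    "label_subgraph",
    "sample_negatives",
    "assemble_features",
]


@dataclass
class GroundTruthNetwork:
    """Directed regulator -> target edges merged from one or more sources."""

    edges: set[tuple[str, str]]
    sources: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    edge_signs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = [e for e in self.edges if e[0] == e[1]]
        if loops:
            logger.info("dropping %d self-loops from the ground truth", len(loops))
            self.edges = {e for e in self.edges if e[0] != e[1]}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        source: str = "unspecified",
        tf_ids: Iterable[str] | None = None,
    ) -> "GroundTruthNetwork":
        edge_set = {(str(a), str(b)) for a, b in edges}
        if tf_ids is not None:
            tfs = set(tf_ids)
            bad = sorted({a for a, _ in edge_set if a not in tfs})
            if bad:
                raise ValueError(f"regulators not in the TF list: {bad}")
        return cls(edges=edge_set, sources={e: {source} for e in edge_set})

    def merge(self, other: "GroundTruthNetwork") -> "GroundTruthNetwork":
        """Union of label sets; source tags retained for reporting only."""
        edges = self.edges | other.edges
        sources: dict[tuple[str, str], set[str]] = {}
        for e in edges:
            sources[e] = self.sources.get(e, set()) | other.sources.get(e, set())
        signs = {**other.edge_signs, **self.edge_signs}
        return GroundTruthNetwork(edges=edges, sources=sources, edge_signs=signs)

    @property
    def regulators(self) -> set[str]:
        return {a for a, _ in self.edges}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["regulator", "target"])


@dataclass
class LabeledSubgraph:
    subgraph: TFAnchoredSubgraph
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]] = field(default_factory=list)
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        nodes = set(self.subgraph.node_ids)
        for s, t in self.positives:
            if s not in nodes or t not in nodes:
                raise ValueError(f"positive ({s}, {t}) leaves the subgraph")


def label_subgraph(
    sg: TFAnchoredSubgraph,
    gt: GroundTruthNetwork,
    expr: ExpressionMatrix | None = None,
) -> LabeledSubgraph | None:
    """Attach ground-truth positives; discard subgraphs with none.

    Positives are the ground-truth edges with both endpoints among the
    subgraph's nodes, direction preserved.  Returns ``None`` when the
    subgraph carries no known regulatory edge.
    """
    nodes = set(sg.node_ids)
    positives = sorted(
        (s, t) for s, t in gt.edges if s in nodes and t in nodes
    )
    if not positives:
        logger.info("discarding subgraph anchored at %s: no ground-truth edges", sg.anchor)
        return None
    features = assemble_features(sg, expr) if expr is not None else None
    return LabeledSubgraph(subgraph=sg, positives=positives, features=features)


def negative_candidates(
    ls: LabeledSubgraph, gt: GroundTruthNetwork
) -> list[tuple[str, str]]:
    """All ordered non-self node pairs of the subgraph outside the ground truth."""
    nodes = ls.subgraph.node_ids
    return [
        (a, b)
        for a in nodes
        for b in nodes
        if a != b and (a, b) not in gt.edges
    ]


def sample_negatives(
    ls: LabeledSubgraph,
    gt: GroundTruthNetwork,
    seed: int,
    candidates: Sequence[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Uniform draw (without replacement) of ``len(positives)`` negatives.

    If fewer candidate pairs exist than positives, all are taken and the
    shortfall is logged.  Intended to be re-seeded each epoch for dynamic
    negative sampling.
    """
    if candidates is None:
        candidates = negative_candidates(ls, gt)
    wanted = len(ls.positives)
    if len(candidates) < wanted:
        logger.warning(
            "subgraph %s: only %d negative candidates for %d positives",
            ls.subgraph.anchor,
            len(candidates),
            wanted,
        )
        return list(candidates)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=wanted, replace=False)
    return [candidates[i] for i in idx]


def assemble_features(
    sg: TFAnchoredSubgraph,
    expr: ExpressionMatrix,
    transform: str | None = "arcsinh",
) -> np.ndarray:
    """Per-subgraph feature block: z-scored expression plus a TF-flag column.

    For each cell (column) the values across the subgraph's genes are scaled
    to mean 0, sd 1 (sd computed over the subgraph genes only; a degenerate
    sd of 0 yields zeros).  The returned block has shape
    ``(n_nodes, n_cells + 1)`` with the TF indicator appended last.
    """
    try:
        rows = [expr.gene_index[g] for g in sg.node_ids]
    except KeyError as exc:
        raise ValueError(f"gene {exc.args[0]!r} missing from the expression matrix") from None
    block = expr.values[rows, :]
    if transform == "arcsinh":
        block = arcsinh_transform(block)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    mean = block.mean(axis=0, keepdims=True)
    sd = block.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (block - mean) / sd, 0.0)
    flags = expr.is_tf[rows].astype(float)[:, None]
    out = np.hstack([z, flags])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values in the assembled feature block")
    return out
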