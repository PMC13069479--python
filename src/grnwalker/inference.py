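"""Whole-network inference: per-subgraph prediction and global aggregation.

Every TF's co-expression neighbourhood is covered by deterministic inference
subgraphs; each is independently feature-assembled, embedded, encoded in
eval mode (z = mu), decoded and reconstructed.  Predictions above the
retention threshold (default 0.3) are kept and aggregated into a global
directed score matrix: each edge's raw score is the mean over contributing
subgraphs of probability x TF-weight (TF-initiated edges weighted up), and
raw scores are min-max normalised to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .gcen import CoexpressionNetwork, ExpressionMatrix
from .supervision import assemble_features
from .training import GRNNet
from .walker import SamplerConfig, enumerate_inference_subgraphs

logger = logging.getLogger(__name__)

__all__ = ["EdgePrediction", "GlobalGRN", "predict_subgraphs", "aggregate"]


@dataclass
class EdgePrediction:
    source: str
    target: str
    probability: float
    subgraph_index: int
    tf_initiated: bool

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-edges are not valid predictions")
        if not 0.0 < self.probability < 1.0:
            raise ValueError("probability must lie strictly in (0, 1)")


@dataclass
class GlobalGRN:
    """Aggregated, min-max-normalised directed TF -> gene score matrix."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def score(self, source: str, target: str, default: float = 0.0) -> float:
        return self.scores.get((source, target), default)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s, t in self.scores:
            out.add(s)
            out.add(t)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (s, t, w, self.counts.get((s, t), 0)) for (s, t), w in self.scores.items()
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "score", "n_subgraphs"])
        return df.sort_values(
            ["score", "source", "target"], ascending=[False, True, True]
        ).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GlobalGRN":
        scores = {(str(r.source), str(r.target)): float(r.score) for r in df.itertuples()}
        counts = (
            {(str(r.source), str(r.target)): int(r.n_subgraphs) for r in df.itertuples()}
            if "n_subgraphs" in df.columns
            else {}
        )
        return cls(scores=scores, counts=counts)


def predict_subgraphs(
    net: GRNNet,
    gcen: CoexpressionNetwork,
    tfs: Sequence[str],
    expr: ExpressionMatrix,
    cfg: RunConfig | None = None,
) -> list[EdgePrediction]:
    """Edge predictions from all deterministic inference subgraphs.

    Only ordered pairs with predicted probability strictly above the
    retention threshold are emitted.
    """
    cfg = cfg or net.cfg
    tf_set = set(tfs)
    sampler = SamplerConfig(subgraph_size=cfg.subgraph_size, mode="infer")
    predictions: list[EdgePrediction] = []
    for idx, sg in enumerate(enumerate_inference_subgraphs(gcen, tfs, sampler)):
        features = assemble_features(sg, expr)
        probs = net.predict_adjacency(features, sg)
        n = sg.n_nodes
        keep = probs > cfg.retention_threshold
        np.fill_diagonal(keep, False)
        ii, jj = np.where(keep)
        for i, j in zip(ii.tolist(), jj.tolist()):
            source, target = sg.node_ids[i], sg.node_ids[j]
            predictions.append(
                EdgePrediction(
                    source=source,
                    target=target,
                    probability=float(probs[i, j]),
                    subgraph_index=idx,
                    tf_initiated=source in tf_set,
                )
            )
    logger.info("retained %d predictions above threshold %.2f", len(predictions), cfg.retention_threshold)
    return predictions


def aggregate(
    predictions: Iterable[EdgePrediction],
    tf_weight: float = 2.0,
    tf_only: bool = True,
) -> GlobalGRN:
    """Sum, average and min-max normalise per-subgraph predictions.

    raw(i -> j) = sum over contributing subgraphs of p * w_tf, divided by
    the number of contributing subgraphs, with w_tf = ``tf_weight`` for
    TF-initiated edges and 1 otherwise.  With ``tf_only`` (default) the
    output is restricted to TF-sourced edges.  When all raw scores are
    equal, every score maps to 1.0 (a single observed edge survives).
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for p in predictions:
        if tf_only and not p.tf_initiated:
            continue
        key = (p.source, p.target)
        w = tf_weight if p.tf_initiated else 1.0
        sums[key] = sums.get(key, 0.0) + p.probability * w
        counts[key] = counts.get(key, 0) + 1
    if not sums:
        return GlobalGRN()
    raw = {k: v / counts[k] for k, v in sums.items()}
    lo, hi = min(raw.values()), max(raw.values())
    if hi - lo <= 0:
        scores = {k: 1.0 for k in raw}
    else:
        scores = {k: (v - lo) / (hi - lo) for k, v in raw.items()}
    return GlobalGRN(scores=scores, counts=counts)
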