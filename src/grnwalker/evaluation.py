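"""Evaluation: clean negative pools, bootstrapped sampled metrics,
full-matrix metrics and early precision.

GRN benchmarks annotate no true negatives, so negatives are drawn from a
*clean pool*: all ordered non-self gene pairs minus every positive of any
split and every negative seen during training/validation.  Sampled metrics
pair the test positives 1:1 with bootstrapped negatives from that pool over
(by default) 100 iterations and average; full-matrix metrics rank the
positives against the entire pool.  Pairs the model abstained on score 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .gcen import ExpressionMatrix, arcsinh_transform, pearson_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CleanNegativePool",
    "MetricReport",
    "build_clean_pool",
    "sampled_metrics",
    "full_matrix_metrics",
    "early_precision",
    "correlation_baseline_scores",
]

Pair = tuple[str, str]


@dataclass
class CleanNegativePool:
    pairs: list[Pair]
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MetricReport:
    sampled_mean: dict[str, float]
    sampled_sd: dict[str, float]
    per_iteration: pd.DataFrame
    iterations: int
    full_auroc: float | None = None
    full_auprc: float | None = None
    early: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sampled_mean": self.sampled_mean,
            "sampled_sd": self.sampled_sd,
            "iterations": self.iterations,
            "full_auroc": self.full_auroc,
            "full_auprc": self.full_auprc,
            "early": self.early,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.per_iteration.to_csv(path, index=False)


def build_clean_pool(
    all_genes: Sequence[str],
    positives_all_splits: Iterable[Pair],
    negatives_train_val: Iterable[Pair] = (),
) -> CleanNegativePool:
    """All ordered non-self pairs minus every exclusion."""
    genes = list(dict.fromkeys(all_genes))
    positives = set(positives_all_splits)
    negatives = set(negatives_train_val)
    excluded = positives | negatives
    pairs = [
        (a, b)
        for a in genes
        for b in genes
        if a != b and (a, b) not in excluded
    ]
    if not pairs:
        raise ValueError("clean negative pool is empty")
    return CleanNegativePool(
        pairs=pairs,
        provenance={
            "genes": len(genes),
            "positives_excluded": len(positives),
            "train_val_negatives_excluded": len(negatives),
        },
    )


def _lookup(scores: Mapping[Pair, float], pairs: Sequence[Pair]) -> np.ndarray:
    # unscored pairs count as 0: the model abstained
    return np.array([scores.get(p, 0.0) for p in pairs], dtype=float)


def _threshold_metrics(y: np.ndarray, s: np.ndarray, threshold: float) -> dict[str, float]:
    pred = s >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    fn = float(np.sum(~pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    accuracy = (tp + tn) / len(y)
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


def sampled_metrics(
    scores: Mapping[Pair, float],
    test_positives: Sequence[Pair],
    pool: CleanNegativePool,
    iterations: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricReport:
    """1:1 bootstrapped negative sampling, averaged over iterations."""
    positives = list(test_positives)
    if not positives:
        raise ValueError("no test positives to evaluate")
    if len(pool) < len(positives):
        raise ValueError(
            f"pool of {len(pool)} pairs cannot supply {len(positives)} negatives"
        )
    pos_scores = _lookup(scores, positives)
    pool_pairs = pool.pairs
    rows = []
    for it in range(iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, it)).generate_state(1)[0] % (2**31 - 1)
        )
        idx = rng.choice(len(pool_pairs), size=len(positives), replace=False)
        neg_scores = _lookup(scores, [pool_pairs[i] for i in idx])
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(positives))])
        s = np.concatenate([pos_scores, neg_scores])
        row = {
            "iteration": it,
            "auroc": float(roc_auc_score(y, s)),
            "auprc": float(average_precision_score(y, s)),
        }
        row.update(_threshold_metrics(y, s, threshold))
        rows.append(row)
    per_iter = pd.DataFrame(rows)
    metrics = [c for c in per_iter.columns if c != "iteration"]
    return MetricReport(
        sampled_mean={m: float(per_iter[m].mean()) for m in metrics},
        sampled_sd={m: float(per_iter[m].std(ddof=0)) for m in metrics},
        per_iteration=per_iter,
        iterations=iterations,
    )


def full_matrix_metrics(
    scores: Mapping[Pair, float],
    test_positives: Sequence[Pair],
    pool: CleanNegativePool,
) -> tuple[float, float]:
    """Ranking metrics over positives against the entire clean pool."""
    positives = list(test_positives)
    if not positives:
        raise ValueError("no test positives to evaluate")
    if not len(pool):
        raise ValueError("empty clean pool")
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(pool))])
    s = np.concatenate([_lookup(scores, positives), _lookup(scores, pool.pairs)])
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def early_precision(
    scores: Mapping[Pair, float],
    ground_truth: Iterable[Pair],
    cutoffs: Sequence[int] = (),
) -> dict[str, float]:
    """EP@k = fraction of the top-k ranked pairs in the ground truth; EPR is
    EP@k at k = #ground-truth edges divided by the ground-truth density of
    the scored pair space."""
    gt = set(ground_truth)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    n_scored = len(ranked)
    if n_scored == 0:
        raise ValueError("no scored pairs")
    out: dict[str, float] = {}
    for k in cutoffs:
        if k > n_scored:
            raise ValueError(f"cutoff {k} exceeds the {n_scored} scored pairs")
        hits = sum(1 for pair, _ in ranked[:k] if pair in gt)
        out[f"EP@{k}"] = hits / k
    k_gt = min(len(gt), n_scored)
    if k_gt == 0:
        raise ValueError("empty ground truth")
    hits = sum(1 for pair, _ in ranked[:k_gt] if pair in gt)
    ep_gt = hits / k_gt
    density = sum(1 for pair, _ in ranked if pair in gt) / n_scored
    out["EP@gt"] = ep_gt
    out["EPR"] = ep_gt / density if density > 0 else 0.0
    return out


def correlation_baseline_scores(
    expr: ExpressionMatrix, pairs: Iterable[Pair] | None = None
) -> dict[Pair, float]:
    """Absolute-Pearson-correlation ranking baseline on arcsinh data."""
    corr = np.abs(pearson_matrix(arcsinh_transform(expr.values)))
    index = expr.gene_index
    if pairs is None:
        genes = expr.gene_ids
        pairs = [(a, b) for a in genes for b in genes if a != b]
    return {
        (a, b): float(corr[index[a], index[b]])
        for a, b in pairs
        if a in index and b in index
    }
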