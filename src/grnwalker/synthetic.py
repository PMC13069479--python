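"""Synthetic ground-truth networks and expression with the statistical
structure the method assumes.

A sparse directed acyclic TF -> target network is drawn (geometric-tailed
out-degrees around a mean, a configurable fraction of repressive edges),
then expression is generated per cell by a linear-Gaussian structural model
propagated in topological order: regulator-free genes are standard normal,
each target is ``effect_size * (signed sum of its regulators) + noise``.  A
softplus maps values to non-negative "counts" and independent dropout zeros
mimic scRNA-seq sparsity.  The defaults (150 genes, 15 TFs, 300 cells,
effect size 1, noise sd 0.5, dropout 0.2) produce regulator-target pairs
clearly more correlated than random pairs — the signal the co-expression
network must capture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .gcen import ExpressionMatrix
from .supervision import GroundTruthNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticGRNSpec",
    "SyntheticDataset",
    "simulate_grn",
    "simulate_expression",
    "simulate_dataset",
    "make_benchmark_split",
]


@dataclass
class SyntheticGRNSpec:
    n_genes: int = 150
    n_tfs: int = 15
    n_cells: int = 300
    edges_per_tf: float = 8.0
    effect_size: float = 1.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.2
    negative_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.edges_per_tf < 1 and self.n_tfs > 0:
            raise ValueError("edges_per_tf must be >= 1")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.n_cells < 2:
            raise ValueError("at least 2 cells are required")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_tfs]


@dataclass
class SyntheticDataset:
    grn: GroundTruthNetwork
    expr: ExpressionMatrix
    tf_ids: list[str]
    spec: SyntheticGRNSpec


def simulate_grn(spec: SyntheticGRNSpec) -> GroundTruthNetwork:
    """Directed acyclic TF -> target network with geometric-tailed out-degrees.

    Targets are drawn from genes later in the (TFs-first) ordering, so the
    network is acyclic by construction; TF -> TF edges are possible.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], float] = {}
    for i in range(spec.n_tfs):
        downstream = genes[i + 1 :]
        if not downstream:
            raise ValueError(f"TF {genes[i]} has no possible targets")
        out_degree = int(rng.geometric(1.0 / spec.edges_per_tf))
        out_degree = min(out_degree, len(downstream))
        targets = rng.choice(len(downstream), size=out_degree, replace=False)
        for t in targets:
            pair = (genes[i], downstream[t])
            edges.add(pair)
            signs[pair] = -1.0 if rng.random() < spec.negative_fraction else 1.0
    return GroundTruthNetwork(
        edges=edges, sources={e: {"synthetic"} for e in edges}, edge_signs=signs
    )


def simulate_expression(grn: GroundTruthNetwork, spec: SyntheticGRNSpec) -> ExpressionMatrix:
    """Linear-Gaussian structural propagation, softplus counts, dropout zeros."""
    genes = spec.gene_ids()
    known = set(genes)
    for s, t in grn.edges:
        if s not in known or t not in known:
            raise ValueError(f"ground-truth edge ({s}, {t}) references unknown genes")
    dag = nx.DiGraph()
    dag.add_nodes_from(genes)
    dag.add_edges_from(grn.edges)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("expression simulation requires an acyclic network")
    order = list(nx.topological_sort(dag))
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)).generate_state(1)[0])

    latent = np.zeros((spec.n_genes, spec.n_cells))
    for g in order:
        i = index[g]
        regulators = list(dag.predecessors(g))
        noise = rng.standard_normal(spec.n_cells)
        if not regulators:
            latent[i] = noise
        else:
            drive = np.zeros(spec.n_cells)
            for r in regulators:
                sign = grn.edge_signs.get((r, g), 1.0)
                drive += sign * latent[index[r]]
            latent[i] = spec.effect_size * drive + spec.noise_sd * noise

    counts = np.logaddexp(0.0, latent)  # softplus: non-negative "counts"
    if spec.dropout_rate > 0:
        mask = rng.random(counts.shape) < spec.dropout_rate
        counts[mask] = 0.0
    cell_ids = [f"C{i + 1:04d}" for i in range(spec.n_cells)]
    is_tf = np.array([g in set(spec.tf_ids()) for g in genes])
    return ExpressionMatrix(values=counts, gene_ids=genes, cell_ids=cell_ids, is_tf=is_tf)


def simulate_dataset(spec: SyntheticGRNSpec) -> SyntheticDataset:
    grn = simulate_grn(spec)
    expr = simulate_expression(grn, spec)
    return SyntheticDataset(grn=grn, expr=expr, tf_ids=spec.tf_ids(), spec=spec)


def make_benchmark_split(
    ds: SyntheticDataset,
    holdout_tf_fraction: float = 0.2,
    val_tf_fraction: float = 0.1,
    seed: int = 0,
) -> dict:
    """Train/validation/test edge splits by anchor TF.

    All edges of a test TF are held out of training and validation entirely,
    mirroring evaluation on regulators never seen during fitting.
    """
    tfs = sorted(ds.grn.regulators)
    if len(tfs) < 3:
        raise ValueError("need at least 3 TFs with edges to split")
    rng = np.random.default_rng(seed)
    order = list(tfs)
    rng.shuffle(order)
    n_test = max(1, int(round(holdout_tf_fraction * len(order))))
    n_val = max(1, int(round(val_tf_fraction * len(order)))) if val_tf_fraction > 0 else 0
    if n_test + n_val >= len(order):
        raise ValueError("holdout and validation fractions leave no training TFs")
    test_tfs = sorted(order[:n_test])
    val_tfs = sorted(order[n_test : n_test + n_val])
    train_tfs = sorted(order[n_test + n_val :])
    by_tf = lambda keep: sorted(e for e in ds.grn.edges if e[0] in set(keep))
    split = {
        "train_tfs": train_tfs,
        "val_tfs": val_tfs,
        "test_tfs": test_tfs,
        "train": by_tf(train_tfs),
        "validation": by_tf(val_tfs),
        "test": by_tf(test_tfs),
    }
    return split


def write_split(split: dict, path: str | Path) -> None:
    serialisable = {
        k: ([list(e) for e in v] if k in ("train", "validation", "test") else v)
        for k, v in split.items()
    }
    Path(path).write_text(json.dumps(serialisable, indent=2))


def read_split(path: str | Path) -> dict:
    raw = json.loads(Path(path).read_text())
    for k in ("train", "validation", "test"):
        raw[k] = [tuple(e) for e in raw.get(k, [])]
    return raw
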