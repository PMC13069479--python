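"""Model/Results facade over the full pipeline.

``GRNModel`` holds the data (expression matrix, TF list, optional ground
truth) and configuration; ``fit()`` builds the co-expression network,
samples and labels TF-anchored subgraphs, trains the network and returns a
``GRNResults`` carrying the fitted parameters, the loss history and the
train/validation split, with ``predict()``, ``evaluate()`` and ``summary()``
methods.

    >>> model = GRNModel(expr, tf_ids, ground_truth=gt)
    >>> res = model.fit()
    >>> grn = res.predict()
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import (
    CleanNegativePool,
    MetricReport,
    build_clean_pool,
    early_precision,
    full_matrix_metrics,
    sampled_metrics,
)
from .gcen import CoexpressionNetwork, ExpressionMatrix, build_gcen
from .inference import GlobalGRN, aggregate, predict_subgraphs
from .supervision import GroundTruthNetwork, label_subgraph
from .training import GRNNet, load_checkpoint, save_checkpoint, train
from .walker import SamplerConfig, sample_training_subgraph

logger = logging.getLogger(__name__)

__all__ = ["GRNModel", "GRNResults"]


class GRNModel:
    """Gene regulatory network inference model bound to one dataset."""

    def __init__(
        self,
        expression: ExpressionMatrix,
        tf_ids: Sequence[str],
        ground_truth: GroundTruthNetwork | None = None,
        config: RunConfig | None = None,
    ):
        self.expression = expression
        self.tf_ids = list(dict.fromkeys(tf_ids))
        self.expression.set_tfs(self.tf_ids)
        self.ground_truth = ground_truth
        self.config = config or RunConfig()
        self._gcen: CoexpressionNetwork | None = None

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        tf_path: str | Path,
        ground_truth_path: str | Path | None = None,
        config: RunConfig | None = None,
        fmt: str | None = None,
    ) -> "GRNModel":
        from .io import read_edge_list, read_expression, read_tf_list

        expr = read_expression(expression_path, fmt)
        tfs = read_tf_list(tf_path)
        gt = None
        if ground_truth_path is not None:
            gt = GroundTruthNetwork.from_edges(
                read_edge_list(ground_truth_path), source=str(ground_truth_path)
            )
        return cls(expr, tfs, ground_truth=gt, config=config)

    # -- pipeline stages ---------------------------------------------------
    @property
    def gcen(self) -> CoexpressionNetwork:
        if self._gcen is None:
            self._gcen = build_gcen(self.expression, self.config.gcen_threshold)
        return self._gcen

    def training_subgraphs(self, anchors: Sequence[str] | None = None):
        sampler = SamplerConfig(
            subgraph_size=self.config.subgraph_size, mode="train", seed=self.config.seed
        )
        anchors = anchors if anchors is not None else self.tf_ids
        out = []
        for tf in anchors:
            if tf not in self.gcen:
                logger.warning("TF %s absent from the co-expression network", tf)
                continue
            sg = sample_training_subgraph(self.gcen, tf, sampler)
            if sg is not None:
                out.append(sg)
        return out

    def fit(
        self,
        train_positives: Iterable[tuple[str, str]] | None = None,
        exclude_tfs: Iterable[str] | None = None,
    ) -> "GRNResults":
        """Train on labelled subgraphs and return a results object.

        ``train_positives`` restricts the supervising edges (e.g. the train
        plus validation edges of a benchmark split); ``exclude_tfs`` drops
        anchors (e.g. held-out test TFs) from training entirely.
        """
        if self.ground_truth is None and train_positives is None:
            raise ValueError("fitting requires a ground-truth network")
        edges = (
            set(train_positives)
            if train_positives is not None
            else set(self.ground_truth.edges)
        )
        gt = GroundTruthNetwork(edges=edges)
        excluded = set(exclude_tfs or ())
        anchors = [tf for tf in self.tf_ids if tf not in excluded]
        labelled = []
        for sg in self.training_subgraphs(anchors):
            ls = label_subgraph(sg, gt, self.expression)
            if ls is not None:
                labelled.append(ls)
        if not labelled:
            raise ValueError("no subgraph carries a ground-truth edge; nothing to train on")
        logger.info("training on %d labelled subgraphs", len(labelled))
        net, history, info = train(labelled, self.config, gt_edges=edges)
        return GRNResults(
            model=self,
            net=net,
            config=self.config,
            history=history,
            train_anchors=info["train_anchors"],
            val_anchors=info["val_anchors"],
            sampled_negatives=info["sampled_negatives"],
            train_positives=edges,
            n_subgraphs=len(labelled),
        )


class GRNResults:
    """Fitted-model results: parameters, history, prediction and evaluation."""

    def __init__(
        self,
        model: GRNModel | None,
        net: GRNNet,
        config: RunConfig,
        history: pd.DataFrame,
        train_anchors: list[str] | None = None,
        val_anchors: list[str] | None = None,
        sampled_negatives: set[tuple[str, str]] | None = None,
        train_positives: set[tuple[str, str]] | None = None,
        n_subgraphs: int = 0,
    ):
        self.model = model
        self.net = net
        self.config = config
        self.history = history
        self.train_anchors = train_anchors or []
        self.val_anchors = val_anchors or []
        self.sampled_negatives = sampled_negatives or set()
        self.train_positives = train_positives or set()
        self.n_subgraphs = n_subgraphs

    # -- prediction --------------------------------------------------------
    def predict(
        self,
        expression: ExpressionMatrix | None = None,
        tf_ids: Sequence[str] | None = None,
        gcen: CoexpressionNetwork | None = None,
    ) -> GlobalGRN:
        """Aggregate per-subgraph predictions into a global GRN.

        Without arguments the model's own dataset is used (zero-shot use
        passes a new expression matrix and TF list).
        """
        if expression is None:
            if self.model is None:
                raise ValueError("no bound dataset; pass an expression matrix")
            expression = self.model.expression
            tf_ids = tf_ids or self.model.tf_ids
            gcen = gcen or self.model.gcen
        else:
            tf_ids = list(tf_ids or expression.tf_ids)
            expression.set_tfs(tf_ids)
            gcen = gcen or build_gcen(expression, self.config.gcen_threshold)
        predictions = predict_subgraphs(self.net, gcen, tf_ids, expression, self.config)
        return aggregate(
            predictions, tf_weight=self.config.tf_weight, tf_only=self.config.tf_only
        )

    # -- evaluation --------------------------------------------------------
    def clean_pool(
        self,
        positives_all_splits: Iterable[tuple[str, str]] | None = None,
        genes: Sequence[str] | None = None,
    ) -> CleanNegativePool:
        if genes is None:
            if self.model is None:
                raise ValueError("no bound dataset; pass the gene universe")
            genes = self.model.expression.gene_ids
        if positives_all_splits is None:
            positives_all_splits = (
                self.model.ground_truth.edges if self.model and self.model.ground_truth else self.train_positives
            )
        return build_clean_pool(genes, positives_all_splits, self.sampled_negatives)

    def evaluate(
        self,
        test_positives: Sequence[tuple[str, str]],
        grn: GlobalGRN | None = None,
        pool: CleanNegativePool | None = None,
        iterations: int | None = None,
        seed: int | None = None,
        cutoffs: Sequence[int] = (),
    ) -> MetricReport:
        """Sampled + full-matrix metrics and early precision on held-out edges."""
        grn = grn if grn is not None else self.predict()
        pool = pool if pool is not None else self.clean_pool()
        report = sampled_metrics(
            grn.scores,
            test_positives,
            pool,
            iterations=iterations or self.config.bootstrap_iterations,
            seed=self.config.seed if seed is None else seed,
            threshold=self.config.eval_threshold,
        )
        report.full_auroc, report.full_auprc = full_matrix_metrics(
            grn.scores, test_positives, pool
        )
        # early precision over the evaluated pair space only
        eval_scores = {
            p: grn.scores.get(p, 0.0) for p in list(test_positives) + pool.pairs
        }
        valid_cutoffs = [k for k in cutoffs if k <= len(eval_scores)]
        report.early = early_precision(eval_scores, set(test_positives), valid_cutoffs)
        return report

    # -- reporting & persistence -------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Gene regulatory network inference results",
            "=" * 58,
        ]
        if self.model is not None:
            expr = self.model.expression
            lines += [
                f"{'Genes:':<28}{expr.n_genes:>10}",
                f"{'Cells:':<28}{expr.n_cells:>10}",
                f"{'Transcription factors:':<28}{len(self.model.tf_ids):>10}",
                f"{'Co-expression edges:':<28}{self.model.gcen.n_edges:>10}",
            ]
        lines += [
            f"{'Labelled subgraphs:':<28}{self.n_subgraphs:>10}",
            f"{'Train / val anchors:':<28}{len(self.train_anchors):>5} /{len(self.val_anchors):>4}",
            f"{'Epochs run:':<28}{len(self.history):>10}",
        ]
        if len(self.history):
            first, last = self.history.iloc[0], self.history.iloc[-1]
            lines += [
                f"{'Train loss (first epoch):':<28}{first['total']:>10.4f}",
                f"{'Train loss (last epoch):':<28}{last['total']:>10.4f}",
                f"{'Best validation loss:':<28}{self.history['val_total'].min():>10.4f}",
            ]
        lines += [
            "-" * 58,
            f"{'Subgraph size:':<28}{cfg.subgraph_size:>10}",
            f"{'Embedding dim / heads:':<28}{cfg.embed_dim:>6} /{cfg.heads:>3}",
            f"{'Latent dim:':<28}{cfg.latent_dim:>10}",
            f"{'Encoder / decoder blocks:':<28}{cfg.encoder_blocks:>6} /{cfg.decoder_blocks:>3}",
            f"{'GCEN threshold:':<28}{cfg.gcen_threshold:>10.2f}",
            f"{'Retention threshold:':<28}{cfg.retention_threshold:>10.2f}",
            f"{'Seed:':<28}{cfg.seed:>10}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.net, self.config)

    @classmethod
    def load(cls, path: str | Path, model: GRNModel | None = None) -> "GRNResults":
        net, cfg = load_checkpoint(path)
        return cls(model=model, net=net, config=cfg, history=pd.DataFrame())
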