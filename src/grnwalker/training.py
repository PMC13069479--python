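"""Optimisation loop for the subgraph link-prediction objective.

Subgraphs are split into train/validation sets by anchor TF (all subgraphs
of a TF stay on one side, preventing anchor leakage), shuffled every epoch,
and optimised with Adam on the composite loss (summed BCE + beta * KL per
subgraph, summed over a batch and divided by the batch size).  Negatives are
resampled every epoch (dynamic negative sampling), the learning rate halves
on a validation plateau, training stops early when validation loss fails to
improve, and the best-validation parameters are restored at the end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .losses import bce_with_logits, kl_term, total_loss
from .nn import Adam, Module, Tensor
from .supervision import LabeledSubgraph, negative_candidates, sample_negatives
from .transcoder import ExpressionEncoder, TranscoderConfig
from .vgae import GraphVAE, TransConvConfig, directed_edge_arrays, reparameterize

logger = logging.getLogger(__name__)

__all__ = ["TrainState", "GRNNet", "train", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainState:
    epoch: int = 0
    best_val: float = np.inf
    patience_left: int = 0
    lr: float = 0.001
    seed: int = 0


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31 - 1))


class GRNNet(Module):
    """Expression encoder composed with the graph variational autoencoder."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.transcoder = ExpressionEncoder(
            TranscoderConfig(cfg.embed_dim, cfg.heads, cfg.negative_slope), rng
        )
        self.vgae = GraphVAE(
            TransConvConfig(
                hidden=cfg.embed_dim,
                heads=cfg.heads,
                encoder_blocks=cfg.encoder_blocks,
                decoder_blocks=cfg.decoder_blocks,
                latent_dim=cfg.latent_dim,
                embed_dim=cfg.embed_dim,
                negative_slope=cfg.negative_slope,
            ),
            rng,
        )

    def forward_pairs(
        self,
        features: np.ndarray,
        src: np.ndarray,
        dst: np.ndarray,
        edge_w: np.ndarray,
        pair_i: np.ndarray,
        pair_j: np.ndarray,
        pair_edge: np.ndarray,
        rng: np.random.Generator | None = None,
    ):
        """Logits for the labelled pairs plus the latent distribution."""
        emb = self.transcoder(Tensor(np.asarray(features, dtype=np.float32)))
        ld = self.vgae.encode(emb, edge_w, src, dst)
        z_node, z_edge = reparameterize(ld, rng, training=self.training)
        z_prime, edge_attn = self.vgae.decode(z_node, z_edge, src, dst)
        logits = self.vgae.pair_logits(z_prime, edge_attn, pair_i, pair_j, pair_edge)
        return logits, ld

    def predict_adjacency(self, features: np.ndarray, sg) -> np.ndarray:
        """Eval-mode probabilistic adjacency for one subgraph (z = mu)."""
        was_training = self.training
        self.eval()
        try:
            src, dst, edge_w = directed_edge_arrays(sg)
            emb = self.transcoder(Tensor(np.asarray(features, dtype=np.float32)))
            ld = self.vgae.encode(emb, edge_w, src, dst)
            z_node, z_edge = reparameterize(ld, training=False)
            z_prime, edge_attn = self.vgae.decode(z_node, z_edge, src, dst)
            epm = self.vgae.reconstruct_adjacency(z_prime, edge_attn, src, dst, sg.node_ids)
        finally:
            self.train(was_training)
        return epm.probabilities


@dataclass
class _Prepared:
    ls: LabeledSubgraph
    src: np.ndarray
    dst: np.ndarray
    edge_w: np.ndarray
    pair_edge_map: dict[tuple[int, int], int]
    candidates: list[tuple[str, str]]
    index: dict[str, int]

    @classmethod
    def build(cls, ls: LabeledSubgraph, gt_edges: set[tuple[str, str]]) -> "_Prepared":
        sg = ls.subgraph
        src, dst, edge_w = directed_edge_arrays(sg)
        index = sg.node_index
        pair_edge_map: dict[tuple[int, int], int] = {}
        for k, (u, v, _) in enumerate(sg.edges):
            pair_edge_map[(index[u], index[v])] = k
            pair_edge_map[(index[v], index[u])] = k
        candidates = [
            (a, b)
            for a in sg.node_ids
            for b in sg.node_ids
            if a != b and (a, b) not in gt_edges
        ]
        return cls(ls, src, dst, edge_w, pair_edge_map, candidates, index)

    def pair_arrays(self, pairs: list[tuple[str, str]]):
        pi = np.array([self.index[a] for a, _ in pairs], dtype=np.int64)
        pj = np.array([self.index[b] for _, b in pairs], dtype=np.int64)
        pe = np.array(
            [self.pair_edge_map.get((i, j), -1) for i, j in zip(pi, pj)], dtype=np.int64
        )
        return pi, pj, pe


def _subgraph_loss(net: GRNNet, prep: _Prepared, negatives, cfg: RunConfig, rng):
    ls = prep.ls
    pairs = list(ls.positives) + list(negatives)
    labels = np.array([1.0] * len(ls.positives) + [0.0] * len(negatives))
    pi, pj, pe = prep.pair_arrays(pairs)
    logits, ld = net.forward_pairs(
        ls.features, prep.src, prep.dst, prep.edge_w, pi, pj, pe, rng
    )
    bce = bce_with_logits(logits, labels)
    kl = kl_term(ld.node_mu, ld.node_log_var) + kl_term(ld.edge_mu, ld.edge_log_var)
    breakdown = total_loss(
        max(float(bce.data), 0.0),
        float(kl.data),
        cfg.beta_mode,
        ls.subgraph.n_nodes,
        cfg.beta_fixed,
    )
    loss = bce + kl * breakdown.beta
    return loss, breakdown


def split_by_anchor(
    dataset: list[LabeledSubgraph], val_fraction: float, seed: int
) -> tuple[list[LabeledSubgraph], list[LabeledSubgraph], list[str], list[str]]:
    anchors = sorted({ls.subgraph.anchor for ls in dataset})
    rng = np.random.default_rng(_derived_seed(seed, 17))
    rng.shuffle(anchors)
    n_val = int(round(val_fraction * len(anchors)))
    if val_fraction > 0 and len(anchors) >= 2:
        n_val = max(n_val, 1)
    val_anchors = set(anchors[:n_val])
    train = [ls for ls in dataset if ls.subgraph.anchor not in val_anchors]
    val = [ls for ls in dataset if ls.subgraph.anchor in val_anchors]
    if not val:
        logger.warning("too few anchors for a validation split; validating on train set")
        val = train
    return train, val, sorted(set(anchors) - val_anchors), sorted(val_anchors)


def train(
    dataset: list[LabeledSubgraph],
    cfg: RunConfig,
    gt_edges: set[tuple[str, str]] | None = None,
    net: GRNNet | None = None,
) -> tuple[GRNNet, pd.DataFrame, dict]:
    """Fit the network; returns (net, per-epoch history, info).

    ``info`` records the train/validation anchor split and every negative
    pair drawn at any epoch (needed later to build clean evaluation pools).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    for ls in dataset:
        if ls.features is None:
            raise ValueError("labelled subgraphs must carry assembled features")
    if gt_edges is None:
        gt_edges = set().union(*(set(ls.positives) for ls in dataset))

    train_set, val_set, train_anchors, val_anchors = split_by_anchor(
        dataset, cfg.val_fraction, cfg.seed
    )
    prep_train = [_Prepared.build(ls, gt_edges) for ls in train_set]
    prep_val = [_Prepared.build(ls, gt_edges) for ls in val_set]

    net = net if net is not None else GRNNet(cfg, np.random.default_rng(cfg.seed))
    opt = Adam(
        net.parameters(),
        lr=cfg.learning_rate,
        l1=cfg.l1_lambda,
        max_grad_norm=cfg.max_grad_norm,
    )
    state = TrainState(lr=cfg.learning_rate, seed=cfg.seed, patience_left=cfg.patience)

    # validation negatives are fixed once for a stable early-stopping signal
    val_negatives = [
        sample_negatives(p.ls, _GT(gt_edges), _derived_seed(cfg.seed, 999_983, k), p.candidates)
        for k, p in enumerate(prep_val)
    ]
    fixed_train_negatives = [
        sample_negatives(p.ls, _GT(gt_edges), _derived_seed(cfg.seed, 424_243, k), p.candidates)
        for k, p in enumerate(prep_train)
    ]

    drawn_negatives: set[tuple[str, str]] = set()
    for negs in val_negatives + fixed_train_negatives:
        drawn_negatives.update(negs)

    rows = []
    best_state: dict[str, np.ndarray] | None = None
    lr_wait = 0
    for epoch in range(cfg.epochs):
        state.epoch = epoch
        order = np.arange(len(prep_train))
        np.random.default_rng(_derived_seed(cfg.seed, 7, epoch)).shuffle(order)
        eps_rng = np.random.default_rng(_derived_seed(cfg.seed, 11, epoch))

        if cfg.resample_negatives:
            epoch_negatives = [
                sample_negatives(
                    p.ls, _GT(gt_edges), _derived_seed(cfg.seed, 13, epoch, k), p.candidates
                )
                for k, p in enumerate(prep_train)
            ]
            for negs in epoch_negatives:
                drawn_negatives.update(negs)
        else:
            epoch_negatives = fixed_train_negatives

        net.train()
        bce_sum = kl_sum = total_sum = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            # per-subgraph backward with gradient accumulation: identical to
            # summing the batch loss, but only one graph lives in memory
            for k in batch:
                loss, breakdown = _subgraph_loss(
                    net, prep_train[k], epoch_negatives[k], cfg, eps_rng
                )
                bce_sum += breakdown.bce
                kl_sum += breakdown.kl
                total_sum += breakdown.total
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or inspect the input features"
                    )
                scaled = loss * (1.0 / len(batch))
                scaled.backward()
                del loss, scaled
            opt.step()

        # validation in eval mode: z = mu, frozen batch-norm statistics
        net.eval()
        val_total = 0.0
        for p, negs in zip(prep_val, val_negatives):
            _, breakdown = _subgraph_loss(net, p, negs, cfg, None)
            val_total += breakdown.total
        if not np.isfinite(val_total):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")

        rows.append(
            {
                "epoch": epoch,
                "bce": bce_sum,
                "kl": kl_sum,
                "total": total_sum,
                "val_total": val_total,
                "lr": opt.lr,
            }
        )
        logger.info(
            "epoch %d: train total %.4f, val total %.4f (lr %.2e)",
            epoch,
            total_sum,
            val_total,
            opt.lr,
        )

        if val_total < state.best_val - 1e-9:
            state.best_val = val_total
            state.patience_left = cfg.patience
            lr_wait = 0
            best_state = net.state_dict()
        else:
            state.patience_left -= 1
            lr_wait += 1
            if lr_wait >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                lr_wait = 0
                logger.info("plateau: learning rate reduced to %.2e", opt.lr)
            if state.patience_left <= 0:
                logger.info("early stopping at epoch %d", epoch)
                break

    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    history = pd.DataFrame(rows)
    info = {
        "train_anchors": train_anchors,
        "val_anchors": val_anchors,
        "sampled_negatives": drawn_negatives,
        "best_val": state.best_val,
        "epochs_run": len(rows),
    }
    return net, history, info


class _GT:
    """Minimal edge-membership view used for negative sampling."""

    def __init__(self, edges: set[tuple[str, str]]):
        self.edges = edges


def save_checkpoint(path: str | Path, net: GRNNet, cfg: RunConfig) -> None:
    state = net.state_dict()
    np.savez(path, __config__=np.array(json.dumps(cfg.to_dict())), **state)


def load_checkpoint(path: str | Path) -> tuple[GRNNet, RunConfig]:
    with np.load(path, allow_pickle=False) as data:
        cfg = RunConfig.from_dict(json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    net = GRNNet(cfg, np.random.default_rng(cfg.seed))
    net.load_state_dict(state)
    net.eval()
    return net, cfg
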