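"""Edge-aware graph-transformer variational autoencoder.

The encoder stacks graph-transformer blocks whose pairwise attention logits
incorporate edge attributes — for genes i, j with edge feature e_ij the
per-head logit is ``q_i^T (k_j + W_e e_ij) / sqrt(d)`` with the softmax taken
over each node's in-neighbourhood — and projects node and edge
representations to the mean and log-variance of a 16-dimensional Gaussian
latent.  Latents are sampled with the reparameterization trick
(``z = mu + sigma * eps``), decoded through further blocks and a small MLP
into regulatory node embeddings Z' and per-edge attention strengths, and the
adjacency is reconstructed as ``sigmoid(<Z'_i, Z'_j> + pooled edge term)``.

Blocks use residual connections, feedforward layers, Leaky ReLU (negative
correlations carry repression signal that a plain ReLU would zero out) and
batch normalization whose statistics are frozen in eval mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    FeedForward,
    Linear,
    Module,
    Tensor,
    concat,
    segment_softmax,
    segment_sum,
)
from .walker import TFAnchoredSubgraph

__all__ = [
    "TransConvConfig",
    "LatentDistribution",
    "EdgeProbabilityMatrix",
    "GraphTransformerLayer",
    "GraphEncoder",
    "GraphDecoder",
    "GraphVAE",
    "pairwise_attention",
    "reparameterize",
    "directed_edge_arrays",
]


@dataclass
class TransConvConfig:
    hidden: int = 64
    heads: int = 4
    encoder_blocks: int = 3
    decoder_blocks: int = 3
    latent_dim: int = 16
    embed_dim: int = 64  # width of the incoming gene embeddings
    out_dim: int = 32  # width of the decoded regulatory embeddings Z'
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.hidden % self.heads != 0:
            raise ValueError("hidden must be divisible by heads")
        if self.encoder_blocks < 1 or self.decoder_blocks < 1:
            raise ValueError("block counts must be >= 1")


@dataclass
class LatentDistribution:
    """Gaussian posterior parameters for node and edge latents."""

    node_mu: Tensor
    node_log_var: Tensor
    edge_mu: Tensor
    edge_log_var: Tensor

    def __post_init__(self) -> None:
        for t in (self.node_mu, self.node_log_var, self.edge_mu, self.edge_log_var):
            if not np.all(np.isfinite(t.data)):
                raise ValueError("non-finite latent parameters")


@dataclass
class EdgeProbabilityMatrix:
    """Per-subgraph predicted regulatory probabilities; diagonal is unused."""

    probabilities: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if self.probabilities.shape != (n, n):
            raise ValueError("probability matrix must be nodes x nodes")
        if not ((self.probabilities > 0) & (self.probabilities < 1)).all():
            raise ValueError("probabilities must lie strictly in (0, 1)")


def directed_edge_arrays(
    sg: TFAnchoredSubgraph,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed message-passing arrays for a subgraph.

    Each undirected edge (u, v, w) contributes the directed pairs u->v and
    v->u (first all forward pairs, then all reverse pairs, so pair k and
    pair k + E describe the same undirected edge).  Returns
    ``(src, dst, weights)`` with node indices and a (2E, 1) weight column.
    """
    index = sg.node_index
    us = np.array([index[u] for u, _, _ in sg.edges], dtype=np.int64)
    vs = np.array([index[v] for _, v, _ in sg.edges], dtype=np.int64)
    ws = np.array([w for _, _, w in sg.edges], dtype=np.float32)
    src = np.concatenate([us, vs])
    dst = np.concatenate([vs, us])
    weights = np.concatenate([ws, ws])[:, None]
    return src, dst, weights


class GraphTransformerLayer(Module):
    """One edge-aware attention block updating node and edge features jointly."""

    def __init__(self, cfg: TransConvConfig, rng: np.random.Generator):
        super().__init__()
        d, h = cfg.hidden, cfg.heads
        self.heads = h
        self.head_dim = d // h
        self.slope = cfg.negative_slope
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.we = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng)
        self.ffn = FeedForward(d, d, rng, self.slope)
        self.bn_node = BatchNorm1d(d)
        self.edge_update = Linear(3 * d, d, rng)
        self.bn_edge = BatchNorm1d(d)

    def _heads(self, t: Tensor, rows: int) -> Tensor:
        return t.reshape(rows, self.heads, self.head_dim)

    def attention(
        self, x: Tensor, e: Tensor, src: np.ndarray, dst: np.ndarray
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Per-head attention weights over each target node's in-neighbourhood."""
        n = x.shape[0]
        m = len(src)
        q = self._heads(self.wq(x), n)
        k = self._heads(self.wk(x), n)
        v = self._heads(self.wv(x), n)
        eh = self._heads(self.we(e), m)
        logits = (q.take(dst) * (k.take(src) + eh)).sum(axis=-1) * (
            1.0 / np.sqrt(self.head_dim)
        )
        alpha = segment_softmax(logits, dst, n)
        return alpha, v, eh

    def attention_weights(
        self, x: Tensor, e: Tensor, src: np.ndarray, dst: np.ndarray
    ) -> np.ndarray:
        alpha, _, _ = self.attention(x, e, src, dst)
        return np.asarray(alpha.data)

    def __call__(
        self, x: Tensor, e: Tensor, src: np.ndarray, dst: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        n = x.shape[0]
        m = len(src)
        alpha, v, eh = self.attention(x, e, src, dst)
        messages = alpha.reshape(m, self.heads, 1) * (v.take(src) + eh)
        agg = segment_sum(messages, dst, n).reshape(n, self.heads * self.head_dim)
        h = x + self.wo(agg)  # residual keeps isolated/self signal
        h = h + self.ffn(h)
        x_out = self.bn_node(h.leaky_relu(self.slope))
        e_mid = self.edge_update(concat([x_out.take(src), x_out.take(dst), e], axis=1))
        e_out = self.bn_edge((e + e_mid).leaky_relu(self.slope))
        return x_out, e_out


def pairwise_attention(
    layer: GraphTransformerLayer,
    x: np.ndarray | Tensor,
    e: np.ndarray | Tensor,
    src: np.ndarray,
    dst: np.ndarray,
) -> np.ndarray:
    """Attention weights a_ij per head; each node's weights sum to 1."""
    def _as_tensor(v):
        if isinstance(v, Tensor):
            return v
        arr = np.asarray(v)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        return Tensor(arr)

    xt, et = _as_tensor(x), _as_tensor(e)
    return layer.attention_weights(xt, et, src, dst)


class GraphEncoder(Module):
    def __init__(self, cfg: TransConvConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.node_in = Linear(cfg.embed_dim, cfg.hidden, rng)
        self.edge_in = Linear(1, cfg.hidden, rng)
        self.blocks = [GraphTransformerLayer(cfg, rng) for _ in range(cfg.encoder_blocks)]
        self.node_mu = Linear(cfg.hidden, cfg.latent_dim, rng)
        self.node_log_var = Linear(cfg.hidden, cfg.latent_dim, rng)
        self.edge_mu = Linear(cfg.hidden, cfg.latent_dim, rng)
        self.edge_log_var = Linear(cfg.hidden, cfg.latent_dim, rng)

    def __call__(
        self, embeddings: Tensor, edge_weights: np.ndarray, src: np.ndarray, dst: np.ndarray
    ) -> LatentDistribution:
        x = self.node_in(embeddings)
        e = self.edge_in(Tensor(np.asarray(edge_weights, dtype=np.float32)))
        for block in self.blocks:
            x, e = block(x, e, src, dst)
        return LatentDistribution(
            node_mu=self.node_mu(x),
            node_log_var=self.node_log_var(x),
            edge_mu=self.edge_mu(e),
            edge_log_var=self.edge_log_var(e),
        )


def reparameterize(
    ld: LatentDistribution,
    seed: int | np.random.Generator | None = None,
    training: bool = True,
) -> tuple[Tensor, Tensor]:
    """Sample ``z = mu + sigma * eps`` (training); return the mean in eval mode."""
    if not training:
        return ld.node_mu, ld.edge_mu
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zs = []
    for mu, log_var in ((ld.node_mu, ld.node_log_var), (ld.edge_mu, ld.edge_log_var)):
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        sigma = (log_var * 0.5).exp()
        zs.append(mu + sigma * Tensor(eps))
    return zs[0], zs[1]


class GraphDecoder(Module):
    def __init__(self, cfg: TransConvConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.node_in = Linear(cfg.latent_dim, cfg.hidden, rng)
        self.edge_in = Linear(cfg.latent_dim, cfg.hidden, rng)
        self.blocks = [GraphTransformerLayer(cfg, rng) for _ in range(cfg.decoder_blocks)]
        self.node_fc1 = Linear(cfg.hidden, cfg.hidden, rng)
        self.node_fc2 = Linear(cfg.hidden, cfg.out_dim, rng)
        self.edge_fc1 = Linear(cfg.hidden, cfg.hidden, rng)
        self.edge_fc2 = Linear(cfg.hidden, 1, rng)

    def __call__(
        self, z_node: Tensor, z_edge: Tensor, src: np.ndarray, dst: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        """Returns updated node embeddings Z' and per-directed-edge attentions."""
        x = self.node_in(z_node)
        e = self.edge_in(z_edge)
        for block in self.blocks:
            x, e = block(x, e, src, dst)
        slope = self.cfg.negative_slope
        z_prime = self.node_fc2(self.node_fc1(x).leaky_relu(slope))
        edge_attn = self.edge_fc2(self.edge_fc1(e).leaky_relu(slope)).reshape(-1)
        return z_prime, edge_attn


class GraphVAE(Module):
    """Encoder, reparameterized sampling, decoder, adjacency reconstruction."""

    def __init__(self, cfg: TransConvConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = GraphEncoder(cfg, rng)
        self.decoder = GraphDecoder(cfg, rng)
        # learned scalar projection of the pooled directed-edge attentions,
        # plus a global logit bias
        self.pool_weight = Tensor(np.ones(1, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)

    # -- pieces ------------------------------------------------------------
    def encode(
        self, embeddings: Tensor, edge_weights: np.ndarray, src: np.ndarray, dst: np.ndarray
    ) -> LatentDistribution:
        return self.encoder(embeddings, edge_weights, src, dst)

    def decode(
        self, z_node: Tensor, z_edge: Tensor, src: np.ndarray, dst: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        return self.decoder(z_node, z_edge, src, dst)

    def pooled_edge_terms(self, edge_attn: Tensor) -> Tensor:
        """Mean of the two directed attentions per undirected edge."""
        m = edge_attn.shape[0]
        half = m // 2
        fwd = edge_attn.take(np.arange(half))
        rev = edge_attn.take(np.arange(half, m))
        return (fwd + rev) * 0.5

    def pair_logits(
        self,
        z_prime: Tensor,
        edge_attn: Tensor,
        pair_i: np.ndarray,
        pair_j: np.ndarray,
        pair_edge: np.ndarray,
    ) -> Tensor:
        """Reconstruction logits for selected ordered pairs.

        ``pair_edge[p]`` is the undirected-edge index carrying pair p's edge
        feature, or -1 when the pair has no co-expression edge (its pooled
        term is 0).
        """
        pooled = self.pooled_edge_terms(edge_attn)
        half = pooled.shape[0]
        padded = concat([pooled, Tensor(np.zeros(1, dtype=np.float32))], axis=0)
        lookup = np.where(pair_edge < 0, half, pair_edge)
        dots = (z_prime.take(pair_i) * z_prime.take(pair_j)).sum(axis=-1)
        return dots + self.pool_weight * padded.take(lookup) + self.bias

    def reconstruct_adjacency(
        self,
        z_prime: Tensor,
        edge_attn: Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        node_ids: list[str],
    ) -> EdgeProbabilityMatrix:
        """Full probabilistic adjacency ``sigmoid(<Z'_i, Z'_j> + pooled term)``."""
        z = np.asarray(z_prime.data, dtype=float)
        logits = z @ z.T
        pooled = np.asarray(self.pooled_edge_terms(edge_attn).data, dtype=float)
        half = len(pooled)
        w = float(self.pool_weight.data[0])
        for k in range(half):
            i, j = int(dst[k]), int(src[k])
            logits[i, j] += w * pooled[k]
            logits[j, i] += w * pooled[k]
        logits += float(self.bias.data[0])
        with np.errstate(over="ignore"):
            probs = 1.0 / (1.0 + np.exp(-logits))
        np.clip(probs, 1e-7, 1.0 - 1e-7, out=probs)
        return EdgeProbabilityMatrix(probabilities=probs, node_ids=list(node_ids))
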