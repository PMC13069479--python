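"""Expression encoder: variable-width expression blocks to fixed embeddings.

Each gene's feature row (its z-scored expression across cells plus the
TF-identity flag) is lifted pointwise from 1 channel to ``embed_dim``
channels by a kernel-1, stride-1 convolution, passed through a single
transformer encoder layer attending over the cell/flag positions, and
mean-pooled over positions into one ``embed_dim`` vector per gene.

No positional encoding is applied over cells: cells are exchangeable
observations, so the embeddings are invariant to cell ordering, and the
output width is independent of the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import FeedForward, LayerNorm, Linear, Module, MultiheadSelfAttention, Tensor

__all__ = ["TranscoderConfig", "GeneEmbeddingBlock", "ExpressionEncoder", "embed_subgraph"]


@dataclass
class TranscoderConfig:
    embed_dim: int = 64
    heads: int = 4
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")


@dataclass
class GeneEmbeddingBlock:
    embeddings: np.ndarray  # nodes x embed_dim
    node_ids: list[str]

    def __post_init__(self) -> None:
        if self.embeddings.shape[0] != len(self.node_ids):
            raise ValueError("one embedding row per node is required")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("non-finite embeddings")


class ExpressionEncoder(Module):
    """Kernel-1 conv lift + one multi-head attention layer + mean pooling."""

    def __init__(self, cfg: TranscoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.embed_dim
        self.lift = Linear(1, d, rng)
        self.attn = MultiheadSelfAttention(d, cfg.heads, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ffn = FeedForward(d, d, rng, cfg.negative_slope)

    def __call__(self, features: Tensor) -> Tensor:
        """``features``: (nodes, cells + 1) -> embeddings (nodes, embed_dim)."""
        if not np.all(np.isfinite(features.data)):
            raise ValueError("non-finite features")
        n, p = features.shape
        x = self.lift(features.reshape(n, p, 1)).leaky_relu(self.cfg.negative_slope)
        h = self.ln1(x + self.attn(x))
        h = self.ln2(h + self.ffn(h))
        return h.mean(axis=1)


def embed_subgraph(
    features: np.ndarray, encoder: ExpressionEncoder, node_ids: list[str] | None = None
) -> GeneEmbeddingBlock:
    """Convenience wrapper producing a :class:`GeneEmbeddingBlock` (eval mode)."""
    was_training = encoder.training
    encoder.eval()
    try:
        out = encoder(Tensor(np.asarray(features, dtype=np.float32)))
    finally:
        encoder.train(was_training)
    ids = node_ids if node_ids is not None else [str(i) for i in range(features.shape[0])]
    return GeneEmbeddingBlock(embeddings=np.asarray(out.data, dtype=float), node_ids=ids)
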