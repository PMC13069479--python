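"""TF-anchored subgraph sampling from the co-expression network.

Training mode expands the neighbourhood of a transcription factor hop by hop
until at least ``subgraph_size - 1`` neighbours are collected (or the
reachable component is exhausted), then takes a single uniform random
selection of ``subgraph_size - 1`` of them.  Inference mode is deterministic:
the same hop expansion, but every collected neighbour is emitted, chunked
into fixed-capacity subgraphs so that coverage is exhaustive.

Node ordering inside a subgraph is reproducible: the anchor first, then
neighbours in sorted-id order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .gcen import CoexpressionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "TFAnchoredSubgraph",
    "collect_neighborhood",
    "sample_training_subgraph",
    "enumerate_inference_subgraphs",
]


@dataclass
class SamplerConfig:
    subgraph_size: int = 100
    mode: str = "train"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.subgraph_size < 2:
            raise ValueError("subgraph_size must be at least 2")
        if self.mode not in ("train", "infer"):
            raise ValueError("mode must be 'train' or 'infer'")
        if self.mode == "train" and self.seed is None:
            raise ValueError("train mode requires a seed")


@dataclass
class TFAnchoredSubgraph:
    """One TF plus its sampled neighbourhood with all induced edges."""

    anchor: str
    node_ids: list[str]
    edges: list[tuple[str, str, float]]
    hop_reached: int
    exhausted: bool = False

    def __post_init__(self) -> None:
        if self.anchor not in self.node_ids:
            raise ValueError("anchor must be one of the subgraph nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.node_ids)}


def collect_neighborhood(
    gcen: CoexpressionNetwork, anchor: str, target: int
) -> tuple[list[str], int, bool]:
    """Breadth-first hop expansion from ``anchor`` until >= ``target`` neighbours.

    Whole hops are collected: expansion stops at the first hop whose
    cumulative neighbour count reaches ``target``, or when the reachable
    component is exhausted.  Returns ``(neighbours, hop_reached, exhausted)``
    with neighbours in breadth-first collection order, anchor excluded.
    """
    if anchor not in gcen:
        raise KeyError(f"anchor {anchor!r} is not in the network")
    visited = {anchor}
    collected: list[str] = []
    frontier = [anchor]
    hop = 0
    while frontier and len(collected) < target:
        hop += 1
        nxt: list[str] = []
        for node in frontier:
            for nb in gcen.neighbors(node):
                if nb not in visited:
                    visited.add(nb)
                    nxt.append(nb)
        collected.extend(nxt)
        frontier = nxt
    if not frontier and len(collected) < target:
        # component exhausted before the target was met
        return collected, hop if collected else 0, True
    return collected, hop, len(collected) < target


def _anchor_seed(seed: int, anchor: str) -> int:
    # stable per-anchor stream derived from the run seed
    return (int(seed) * 1_000_003 + zlib.crc32(anchor.encode())) % (2**31 - 1)


def sample_training_subgraph(
    gcen: CoexpressionNetwork, anchor: str, cfg: SamplerConfig
) -> TFAnchoredSubgraph | None:
    """Fixed-size stochastic subgraph around ``anchor`` (training mode).

    Returns ``None`` (with a logged reason) when the anchor is isolated.
    When the reachable component is smaller than the target, the smaller
    subgraph is emitted rather than discarded.
    """
    if cfg.mode != "train":
        raise ValueError("sample_training_subgraph requires mode='train'")
    neighbours, hop, exhausted = collect_neighborhood(gcen, anchor, cfg.subgraph_size - 1)
    if not neighbours:
        logger.info("skipping %s: isolated in the co-expression network", anchor)
        return None
    keep = cfg.subgraph_size - 1
    if len(neighbours) > keep:
        rng = np.random.default_rng(_anchor_seed(cfg.seed, anchor))
        chosen_idx = rng.choice(len(neighbours), size=keep, replace=False)
        chosen = [neighbours[i] for i in chosen_idx]
    else:
        chosen = list(neighbours)
    node_ids = [anchor] + sorted(chosen)
    return TFAnchoredSubgraph(
        anchor=anchor,
        node_ids=node_ids,
        edges=gcen.induced_edges(node_ids),
        hop_reached=hop,
        exhausted=exhausted,
    )


def enumerate_inference_subgraphs(
    gcen: CoexpressionNetwork,
    tfs: Sequence[str],
    cfg: SamplerConfig | None = None,
) -> Iterator[TFAnchoredSubgraph]:
    """Deterministic, exhaustive subgraph enumeration for inference.

    Every collected neighbour of every TF appears in at least one subgraph:
    neighbours are chunked in collection order into groups of at most
    ``subgraph_size - 1``, with the anchor prepended to each chunk.  Genes
    recurring across subgraphs are treated as context-specific instances.
    """
    cfg = cfg or SamplerConfig(mode="infer")
    if cfg.mode != "infer":
        raise ValueError("enumerate_inference_subgraphs requires mode='infer'")
    capacity = cfg.subgraph_size - 1
    for anchor in tfs:
        if anchor not in gcen:
            logger.warning("TF %s absent from the network; skipped", anchor)
            continue
        neighbours, hop, _ = collect_neighborhood(gcen, anchor, capacity)
        if not neighbours:
            logger.info("skipping %s: isolated in the co-expression network", anchor)
            continue
        for start in range(0, len(neighbours), capacity):
            chunk = neighbours[start : start + capacity]
            node_ids = [anchor] + sorted(chunk)
            yield TFAnchoredSubgraph(
                anchor=anchor,
                node_ids=node_ids,
                edges=gcen.induced_edges(node_ids),
                hop_reached=hop,
            )
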