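"""Run configuration shared by every pipeline stage.

A single :class:`RunConfig` carries the co-expression threshold, sampler,
architecture and optimisation hyperparameters so that a trained checkpoint can
be reloaded with exactly the settings that produced it.  The defaults are the
published operating point of the method (threshold 0.1, subgraphs of 100
genes, 64-dim embeddings with 4 heads, 16-dim latent, Adam at 1e-3, batches of
8, KL weight 1/#genes, retention 0.3, 100 bootstrap iterations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig"]

_BETA_MODES = ("per_gene", "fixed")


@dataclass
class RunConfig:
    # co-expression network
    gcen_threshold: float = 0.1
    # sampler
    subgraph_size: int = 100
    # architecture
    embed_dim: int = 64
    latent_dim: int = 16
    heads: int = 4
    encoder_blocks: int = 3
    decoder_blocks: int = 3
    negative_slope: float = 0.01
    # optimisation
    learning_rate: float = 0.001
    batch_size: int = 8
    epochs: int = 100
    beta_mode: str = "per_gene"
    beta_fixed: float = 0.01
    l1_lambda: float = 1e-5
    patience: int = 10
    lr_patience: int = 5
    lr_factor: float = 0.5
    max_grad_norm: float = 5.0
    val_fraction: float = 0.1
    resample_negatives: bool = True
    # inference / aggregation
    retention_threshold: float = 0.3
    tf_weight: float = 2.0
    tf_only: bool = True
    # evaluation
    bootstrap_iterations: int = 100
    eval_threshold: float = 0.5
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("gcen_threshold", "retention_threshold", "eval_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")
        for name in (
            "subgraph_size",
            "embed_dim",
            "latent_dim",
            "heads",
            "encoder_blocks",
            "decoder_blocks",
            "batch_size",
            "epochs",
            "bootstrap_iterations",
            "patience",
            "lr_patience",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.subgraph_size < 2:
            raise ValueError("subgraph_size must be at least 2")
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        if self.beta_mode not in _BETA_MODES:
            raise ValueError(f"beta_mode must be one of {_BETA_MODES}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.beta_fixed <= 0:
            raise ValueError("beta_fixed must be positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
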