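"""Composite training objective: reconstruction BCE plus weighted KL.

Per subgraph v the reconstruction term is the *summed* binary cross-entropy
over its labelled pairs,

    L_BCE(v) = -sum_(i,j) [ y_ij log(p_ij) + (1 - y_ij) log(1 - p_ij) ],

the latent regulariser is the closed-form KL divergence to a standard
normal prior,

    L_KL(v) = 1/2 sum_k [ mu_k^2 + sigma_k^2 - log(sigma_k^2) - 1 ],

and the total is L_BCE + beta * L_KL with beta = 1/#genes in the subgraph
(default) or a fixed constant (0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossBreakdown", "bce_loss", "kl_divergence", "total_loss", "bce_with_logits", "kl_term"]

EPS = 1e-7


@dataclass
class LossBreakdown:
    bce: float
    kl: float
    beta: float
    total: float

    def __post_init__(self) -> None:
        for name in ("bce", "kl", "beta", "total"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite loss component {name}")


def bce_loss(probabilities: np.ndarray, labels: np.ndarray, eps: float = EPS) -> float:
    """Summed binary cross-entropy over labelled pairs (probabilities clipped)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same shape")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be in {0, 1}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def kl_divergence(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL(N(mu, sigma^2) || N(0, I)), summed over all latent components."""
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
        raise ValueError("non-finite latent parameters")
    return float(0.5 * (mu**2 + np.exp(log_var) - log_var - 1.0).sum())


def total_loss(
    bce: float,
    kl: float,
    beta_mode: str = "per_gene",
    subgraph_gene_count: int | None = None,
    beta_fixed: float = 0.01,
) -> LossBreakdown:
    if bce < 0 or kl < 0:
        raise ValueError("loss components must be non-negative")
    if beta_mode == "per_gene":
        if not subgraph_gene_count:
            raise ValueError("per_gene beta requires a positive subgraph gene count")
        beta = 1.0 / subgraph_gene_count
    elif beta_mode == "fixed":
        beta = beta_fixed
    else:
        raise ValueError(f"unknown beta_mode {beta_mode!r}")
    return LossBreakdown(bce=bce, kl=kl, beta=beta, total=bce + beta * kl)


# -- differentiable versions used inside the training loop ------------------


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable summed BCE on logits.

    Identical to ``bce_loss(sigmoid(logits), labels)`` up to the clipping
    epsilon: softplus(l) - y*l = -[y log p + (1-y) log(1-p)].
    """
    y = np.asarray(labels, dtype=logits.data.dtype)
    return (logits.softplus() - logits * Tensor(y)).sum()


def kl_term(mu: Tensor, log_var: Tensor) -> Tensor:
    return ((mu * mu + log_var.exp() - log_var - 1.0) * 0.5).sum()
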