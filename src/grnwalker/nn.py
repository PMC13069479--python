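"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the package's compute engine: a small tape-based autodiff ``Tensor``
with exactly the operations the expression encoder and the graph
variational autoencoder need (broadcast arithmetic, batched matmul, softmax,
segment reductions for message passing), plus the layers (linear, layer/batch
norm, multi-head self-attention) and an Adam optimiser with optional L1
penalty and global-norm gradient clipping.

Float32 is used for learned parameters; operations preserve the dtype of
their inputs, so float64 graphs (used by gradient checks) stay float64.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "FeedForward",
    "MultiheadSelfAttention",
    "Adam",
    "concat",
    "segment_sum",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        if isinstance(data, (np.ndarray, np.generic)):
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if grad.dtype == self.data.dtype and grad.flags.owndata and grad.flags.writeable:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # python scalars are weak: they adopt the host tensor's dtype
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other, dtype=float))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = back
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape: int):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g.reshape(orig)) if self.requires_grad else None
        )
        return out

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g.transpose(inv)) if self.requires_grad else None
        )
        return out

    def take(self, indices: np.ndarray):
        """Row gather along axis 0 with integer indices."""
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], _parents=(self,))

        def back(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        out._backward = back
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis=axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            denom = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * val) if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g / self.data) if self.requires_grad else None
        )
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * 0.5 / val) if self.requires_grad else None
        )
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, _parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * val * (1.0 - val)) if self.requires_grad else None
        )
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)))

        out._backward = back
        return out

    def leaky_relu(self, negative_slope: float = 0.01):
        mask = self.data >= 0
        out = Tensor(np.where(mask, self.data, negative_slope * self.data), _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(np.where(mask, g, negative_slope * g))

        out._backward = back
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, _parents=(self,))

        def back(g):
            if self.requires_grad:
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accumulate(val * (g - dot))

        out._backward = back
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = back
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    seg = np.asarray(segments)
    acc = np.zeros((num_segments,) + x.data.shape[1:], dtype=x.data.dtype)
    np.add.at(acc, seg, x.data)
    out = Tensor(acc, _parents=(x,))
    out._backward = lambda g: x._accumulate(g[seg]) if x.requires_grad else None
    return out


def segment_softmax(
    logits: Tensor, segments: np.ndarray, num_segments: int, eps: float = 1e-12
) -> Tensor:
    """Softmax of ``logits`` within each segment (per-node attention weights).

    Rows whose segment has no entries simply never occur; segments present
    sum to 1.  The max-shift uses detached values, so gradients match the
    exact softmax.
    """
    seg = np.asarray(segments)
    shift = np.full((num_segments,) + logits.data.shape[1:], -np.inf, dtype=logits.data.dtype)
    np.maximum.at(shift, seg, logits.data)
    shifted = logits - Tensor(shift[seg])
    e = shifted.exp()
    denom = segment_sum(e, seg, num_segments)
    return e / (denom.take(seg) + eps)


# ---------------------------------------------------------------------------
# modules


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)).astype(np.float32)


class Module:
    def __init__(self) -> None:
        self.training = True

    # -- traversal ---------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- persistence -------------------------------------------------------
    def _buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child._buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self._buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:") :]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = value.astype(p.data.dtype).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        norm = xc / ((var + self.eps) ** 0.5)
        return norm * self.gamma + self.beta


class BatchNorm1d(Module):
    """Normalisation over the node/edge axis (axis 0) of a 2-D block.

    Graphs differ wildly between subgraphs, so by default the statistics of
    the *current* block are used in eval mode as well (deterministic for a
    given input); running statistics are tracked and can be frozen in eval
    with ``use_running_stats=True``.
    """

    def __init__(
        self,
        dim: int,
        momentum: float = 0.1,
        eps: float = 1e-5,
        use_running_stats: bool = False,
    ):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.use_running_stats = use_running_stats

    def __call__(self, x: Tensor) -> Tensor:
        if self.training or not self.use_running_stats:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            if self.training:
                m = self.momentum
                self.running_mean = (
                    (1 - m) * self.running_mean + m * mu.data.ravel()
                ).astype(self.running_mean.dtype)
                self.running_var = (
                    (1 - m) * self.running_var + m * var.data.ravel()
                ).astype(self.running_var.dtype)
            norm = xc / ((var + self.eps) ** 0.5)
        else:
            norm = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return norm * self.gamma + self.beta


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator, negative_slope: float = 0.01):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).leaky_relu(self.negative_slope))


class MultiheadSelfAttention(Module):
    """Standard multi-head self-attention over the second-to-last axis."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, n: int, p: int) -> Tensor:
        # (N, P, D) -> (N, H, P, dh)
        return x.reshape(n, p, self.heads, self.head_dim).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        n, p, _ = x.shape
        q = self._split(self.wq(x), n, p)
        k = self._split(self.wk(x), n, p)
        v = self._split(self.wv(x), n, p)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(n, p, self.dim)
        return self.wo(out)


class Adam:
    """Adam with optional L1 penalty (subgradient) and global-norm clipping."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        l1: float = 0.0,
        max_grad_norm: float | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.l1 = l1
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [
            (p.grad if p.grad is not None else np.zeros_like(p.data)) for p in self.params
        ]
        if self.l1:
            grads = [g + self.l1 * np.sign(p.data) for g, p in zip(grads, self.params)]
        if self.max_grad_norm is not None:
            total = math.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
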