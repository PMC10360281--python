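"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (a few hundred thousand parameters) and is
trained on CPU, so a compact tape-based engine over float64 ``numpy`` arrays is
all that is needed.  Only the primitives the model uses are implemented:
elementwise arithmetic, matmul, exp/log/relu/sqrt, axis reductions, row
gather/scatter and segment sums.  Higher-level pieces (layer norm, segment
softmax, cosine similarity, dropout) are composed from these primitives so
their gradients come for free.

Gradients are accumulated in ``Tensor.grad`` as plain ndarrays after calling
``backward()`` on a scalar.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "exp",
    "log",
    "relu",
    "sqrt",
    "power",
    "tsum",
    "tmean",
    "transpose",
    "reshape",
    "gather_rows",
    "take2d",
    "segment_sum",
    "segment_mean",
    "segment_softmax",
    "layer_norm",
    "batch_norm",
    "linear",
    "dropout",
    "row_norms",
    "cosine_matrix",
    "logsumexp_rows",
    "glorot",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph traversal ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: molecule batches can make deep graphs
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(other, power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def matmul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            _accum(a, g @ b.data.T)
        if b.requires_grad:
            _accum(b, a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bw)


def power(a, p: float) -> Tensor:
    a = constant(a)
    out_data = a.data ** p

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return Tensor(out_data, parents=(a,), backward=bw)


def exp(a) -> Tensor:
    a = constant(a)
    out_data = np.exp(a.data)

    def bw(g):
        _accum(a, g * out_data)

    return Tensor(out_data, parents=(a,), backward=bw)


def log(a) -> Tensor:
    a = constant(a)
    out_data = np.log(a.data)

    def bw(g):
        _accum(a, g / a.data)

    return Tensor(out_data, parents=(a,), backward=bw)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def relu(a) -> Tensor:
    a = constant(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bw(g):
        _accum(a, g * mask)

    return Tensor(out_data, parents=(a,), backward=bw)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = constant(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(gg, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bw)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = constant(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = constant(a)
    old_shape = a.data.shape

    def bw(g):
        _accum(a, g.reshape(old_shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=bw)


def transpose(a) -> Tensor:
    a = constant(a)

    def bw(g):
        _accum(a, g.T)

    return Tensor(a.data.T, parents=(a,), backward=bw)


def gather_rows(a, idx) -> Tensor:
    """out[i] = a[idx[i]] along axis 0; backward scatter-adds."""
    a = constant(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            _accum(a, buf)

    return Tensor(out_data, parents=(a,), backward=bw)


def take2d(a, rows, cols) -> Tensor:
    """out[i] = a[rows[i], cols[i]] (1-D result)."""
    a = constant(a)
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    out_data = a.data[rows, cols]

    def bw(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, (rows, cols), g)
            _accum(a, buf)

    return Tensor(out_data, parents=(a,), backward=bw)


def segment_sum(a, seg_ids, num_segments: int) -> Tensor:
    """Row-wise sum of ``a`` grouped by ``seg_ids`` into ``num_segments`` rows."""
    a = constant(a)
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out_shape = (num_segments,) + a.data.shape[1:]
    out_data = np.zeros(out_shape, dtype=np.float64)
    np.add.at(out_data, seg_ids, a.data)

    def bw(g):
        _accum(a, g[seg_ids])

    return Tensor(out_data, parents=(a,), backward=bw)


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def segment_mean(a, seg_ids, num_segments: int) -> Tensor:
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    counts = np.bincount(seg_ids, minlength=num_segments).astype(np.float64)
    counts[counts == 0] = 1.0
    inv = 1.0 / counts
    s = segment_sum(a, seg_ids, num_segments)
    if s.ndim == 2:
        inv = inv[:, None]
    return mul(s, inv)


def segment_softmax(logits, seg_ids, num_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector within each segment.

    The per-segment max is subtracted as a detached constant for numerical
    stability; this does not change the gradient.
    """
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, seg_ids, constant(logits).data)
    shifted = add(logits, -seg_max[seg_ids])
    e = exp(shifted)
    denom = gather_rows(segment_sum(e, seg_ids, num_segments), seg_ids)
    return mul(e, power(denom, -1.0))


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-row normalization over the feature axis with learned scale/shift."""
    mu = tmean(x, axis=1, keepdims=True)
    xc = add(x, mul(mu, -1.0))
    var = tmean(mul(xc, xc), axis=1, keepdims=True)
    xhat = mul(xc, power(add(var, eps), -0.5))
    return add(mul(xhat, gamma), beta)


def batch_norm(
    x,
    gamma,
    beta,
    running_mean: Tensor,
    running_var: Tensor,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-feature batch normalization with running statistics.

    In train mode the batch statistics are used (and the running buffers
    updated in place, outside the gradient tape); in eval mode the stored
    running statistics are applied as constants, making the output of each
    row independent of the rest of the batch.
    """
    x = constant(x)
    if train:
        mu = tmean(x, axis=0, keepdims=True)
        xc = add(x, mul(mu, -1.0))
        var = tmean(mul(xc, xc), axis=0, keepdims=True)
        running_mean.data = (1 - momentum) * running_mean.data + momentum * mu.data[0]
        running_var.data = (1 - momentum) * running_var.data + momentum * var.data[0]
        xhat = mul(xc, power(add(var, eps), -0.5))
    else:
        xhat = mul(add(x, -running_mean.data), (running_var.data + eps) ** -0.5)
    return add(mul(xhat, gamma), beta)


def linear(x, w, b=None) -> Tensor:
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out


def dropout(x, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return constant(x)
    keep = (rng.random(constant(x).shape) >= p) / (1.0 - p)
    return mul(x, keep)


def row_norms(x, eps: float = 1e-12) -> Tensor:
    return power(add(tsum(mul(x, x), axis=1, keepdims=True), eps), 0.5)


def cosine_matrix(a, b) -> Tensor:
    """Pairwise cosine similarities between rows of ``a`` and rows of ``b``."""
    an = mul(a, power(row_norms(a), -1.0))
    bn = mul(b, power(row_norms(b), -1.0))
    return matmul(an, transpose(bn))


def logsumexp_rows(x) -> Tensor:
    m = constant(x).data.max(axis=1, keepdims=True)
    s = tsum(exp(add(x, -m)), axis=1)
    return add(log(s), m[:, 0])


# ---------------------------------------------------------------------------
# initialization and optimization
# ---------------------------------------------------------------------------

def glorot(rng: np.random.Generator, shape: Sequence[int]) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[1] if len(shape) > 1 else shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            # global-norm clipping guards against rare gradient spikes (the
            # cosine critic's gradient grows as 1/||x|| when a pooled view
            # nearly cancels to zero)
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params.values() if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params.values():
                    if p.grad is not None:
                        p.grad *= scale
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
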