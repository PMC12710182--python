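"""Compact reverse-mode automatic differentiation on numpy arrays.

A tape-based engine providing exactly the operations the sequence
regressors need: broadcast-aware add/mul, batched matmul, embedding
lookup, layer normalization, softmax, activations, masked mean pooling,
time-step slicing, dropout and an MAE loss, plus an Adam optimizer.
Gradients are verified against central finite differences in the test
suite.  float32 throughout; determinism comes from seeding every RNG.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        # safe without copying: grad arrays are only ever rebound, never
        # mutated in place
        t.grad = g if g.dtype == DTYPE else g.astype(DTYPE)
    else:
        t.grad = t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))
    out._backward = lambda g: (
        _accum(a, _unbroadcast(g, a.shape)),
        _accum(b, _unbroadcast(g, b.shape)),
    )
    return out


def mul(a: Tensor, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))
    out._backward = lambda g: (
        _accum(a, _unbroadcast(g * b.data, a.shape)),
        _accum(b, _unbroadcast(g * a.data, b.shape)),
    )
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, parents=(a,))
    out._backward = lambda g: _accum(a, g * c)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting on leading axes."""
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        _accum(a, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        _accum(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: _accum(a, g.reshape(a.shape))
    return out


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), parents=(a,))
    out._backward = lambda g: _accum(a, g.transpose(inv))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, parents=(a,))
    out._backward = lambda g: _accum(a, g * (1.0 - y * y))
    return out


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, parents=(a,))
    out._backward = lambda g: _accum(a, g * y * (1.0 - y))
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup: out[..., :] = weight[indices[...], :]."""
    idx = np.asarray(indices)
    out = Tensor(weight.data[idx], parents=(weight,))

    def backward(g):
        dw = np.zeros_like(weight.data)
        np.add.at(dw, idx, g)
        _accum(weight, dw)

    out._backward = backward
    return out


def softmax_last(a: Tensor, bias: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``bias`` is an additive constant
    (e.g. -1e9 at masked attention keys) outside the gradient path."""
    z = a.data if bias is None else a.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, parents=(a,))

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        _accum(a, y * (g - dot))

    out._backward = backward
    return out


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale/shift."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, parents=(a, gamma, beta))

    def backward(g):
        reduce_axes = tuple(range(g.ndim - 1))
        _accum(gamma, (g * xhat).sum(axis=reduce_axes))
        _accum(beta, g.sum(axis=reduce_axes))
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        _accum(a, inv * (dxhat - m1 - xhat * m2))

    out._backward = backward
    return out


def masked_mean(a: Tensor, mask: np.ndarray) -> Tensor:
    """Average (B, L, D) over the L axis using a (B, L) 0/1 mask.

    An all-zero mask row is guarded (denominator clamped to 1), so fully
    padded inputs still give a finite result.
    """
    m = np.asarray(mask, dtype=DTYPE)
    denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)  # (B, 1)
    out_data = (a.data * m[:, :, None]).sum(axis=1) / denom
    out = Tensor(out_data, parents=(a,))

    def backward(g):
        _accum(a, g[:, None, :] * (m / denom)[:, :, None])

    out._backward = backward
    return out


def time_slice(a: Tensor, t: int) -> Tensor:
    """Pick time step ``t`` from a (B, L, D) tensor -> (B, D)."""
    out = Tensor(a.data[:, t, :], parents=(a,))

    def backward(g):
        da = np.zeros_like(a.data)
        da[:, t, :] = g
        _accum(a, da)

    out._backward = backward
    return out


def narrow(a: Tensor, start: int, size: int) -> Tensor:
    """Contiguous slice along the last axis."""
    out = Tensor(a.data[..., start : start + size], parents=(a,))

    def backward(g):
        da = np.zeros_like(a.data)
        da[..., start : start + size] = g
        _accum(a, da)

    out._backward = backward
    return out


def row_slice(a: Tensor, size: int) -> Tensor:
    """Leading slice a[:size] along the first axis."""
    out = Tensor(a.data[:size], parents=(a,))

    def backward(g):
        da = np.zeros_like(a.data)
        da[:size] = g
        _accum(a, da)

    out._backward = backward
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.shape) >= p).astype(DTYPE) / (1.0 - p)
    return mul(a, Tensor(keep))


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error against a constant target vector."""
    t = np.asarray(target, dtype=DTYPE)
    diff = pred.data - t
    out = Tensor(np.abs(diff).mean(), parents=(pred,))
    out._backward = lambda g: _accum(pred, g * np.sign(diff) / diff.size)
    return out


class Adam:
    """Adam optimizer (decoupled weight decay, AdamW-style) over a
    name -> Tensor parameter mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / b1c
            vhat = self.v[key] / b2c
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                step = step + self.lr * self.weight_decay * p.data
            p.data = p.data - step.astype(DTYPE)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones(shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)
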