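"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operator set the dual-encoder model needs: broadcasted
arithmetic, (batched) matmul, 1-D convolution and max-pooling, the sigmoid /
ReLU family, axis reductions, softmax / logsumexp, indexing, concatenation and
reshaping — plus an Adam/SGD optimizer and a tiny ``Module`` parameter
registry.  Everything runs in float64 so training is bit-reproducible on a
single thread and finite-difference gradient checks are meaningful.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "maxpool1d",
    "softmax",
    "logsumexp",
    "dropout",
    "Module",
    "Adam",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ---- basic properties -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ---- backprop ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            # leaves that also have parents do not occur in this engine

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            return ((self, g * p * self.data ** (p - 1.0)),)

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.data.shape)),
                    (other, _unbroadcast(gb, other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    # ---- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            return ((self, g / self.data),)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            return ((self, g * mask),)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)

        def bw(g):
            return ((self, g * scale),)

        return Tensor._make(self.data * scale, (self,), bw)

    # ---- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)  # first max wins on ties: deterministic

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            return ((self, gx),)

        return Tensor._make(out_data, (self,), bw)

    # ---- shape manipulation -----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            return ((self, g.reshape(orig)),)

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return ((self, gx),)

        return Tensor._make(out_data, (self,), bw)

    # ---- misc -------------------------------------------------------------
    def l2_normalize(self, axis: int = -1, eps: float = 1e-12):
        norm = (self * self).sum(axis=axis, keepdims=True) ** 0.5
        return self / (norm + eps)

    def item(self) -> float:
        return float(self.data)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))

    return Tensor._make(out_data, tuple(tensors), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """Cross-correlation along the last axis.

    x: (B, C_in, L); w: (C_out, C_in, K); b: (C_out,).  Returns
    (B, C_out, L_out) with L_out = (L + 2*padding - K) // stride + 1.
    """
    x = Tensor.as_tensor(x)
    w = Tensor.as_tensor(w)
    K = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    L = xp.shape[-1]
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel {K}")
    cols = sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]  # (B,Cin,Lout,K)
    out_data = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def bw(g):
        grads = []
        if x.requires_grad:
            gcols = np.einsum("bol,ock->bclk", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            Lout = g.shape[-1]
            for k in range(K):
                gxp[:, :, k:k + stride * Lout:stride] += gcols[:, :, :, k]
            gx = gxp[:, :, padding:gxp.shape[-1] - padding] if padding else gxp
            grads.append((x, gx))
        if w.requires_grad:
            gw = np.einsum("bol,bclk->ock", g, cols, optimize=True)
            grads.append((w, gw))
        if b is not None and b.requires_grad:
            grads.append((b, g.sum(axis=(0, 2))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bw)


def maxpool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling (stride == kernel) along the last axis."""
    x = Tensor.as_tensor(x)
    B, C, L = x.data.shape
    Lout = L // kernel
    view = x.data[:, :, :Lout * kernel].reshape(B, C, Lout, kernel)
    out_data = view.max(axis=-1)
    idx = view.argmax(axis=-1)

    def bw(g):
        gview = np.zeros_like(view)
        np.put_along_axis(gview, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :Lout * kernel] = gview.reshape(B, C, Lout * kernel)
        return ((x, gx),)

    return Tensor._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor.as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((x, s * (g - dot)),)

    return Tensor._make(s, (x,), bw)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor.as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    ssum = e.sum(axis=axis, keepdims=True)
    out_data = np.squeeze(np.log(ssum) + m, axis=axis)

    def bw(g):
        g = np.expand_dims(np.asarray(g), axis)
        return ((x, g * (e / ssum)),)

    return Tensor._make(out_data, (x,), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or p == 0."""
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# parameter containers and optimizers
# ---------------------------------------------------------------------------

class Module:
    """Parameter registry: walks attributes to collect trainable tensors."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value
            elif isinstance(value, Module):
                for k, v in value.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Linear(Module):
    """Affine layer; He-style fan-in uniform init keeps activation variance
    roughly constant through deep ReLU-family stacks."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.w = Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)
        bias_bound = 1.0 / np.sqrt(n_in)
        self.b = Tensor(rng.uniform(-bias_bound, bias_bound, n_out),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """1-D convolution layer; He-style fan-in uniform init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, *, rng: np.random.Generator):
        fan_in = c_in * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.w = Tensor(rng.uniform(-bound, bound, (c_out, c_in, kernel)),
                        requires_grad=True)
        bias_bound = 1.0 / np.sqrt(fan_in)
        self.b = Tensor(rng.uniform(-bias_bound, bias_bound, c_out),
                        requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class SGD:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params.values():
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
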