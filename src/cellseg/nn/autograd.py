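"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the small residual U-net in this package:
a :class:`Tensor` wrapping a float32 array, a handful of primitive ops
with hand-written vector-Jacobian products, and topological-order
backprop. Everything runs on the CPU in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "matmul", "relu", "leaky_relu", "reshape",
    "conv2d", "maxpool2", "upsample2", "global_avg_pool",
    "l2_normalize_rows", "channel_slice", "batchnorm_train", "affine_channels",
    "mean_square", "bce_with_logits",
]


class Tensor:
    """A numpy array plus the graph edges needed for backprop."""

    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        arr = np.asarray(data, dtype=np.float32)
        # note: ascontiguousarray would promote 0-d scalars to 1-d
        self.data = np.ascontiguousarray(arr) if arr.ndim else arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self.parents: tuple["Tensor", ...] = ()
        self.bwd = None  # callable(grad_out) -> tuple of parent grads
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backprop from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.bwd is None or node.grad is None:
                continue
            grads = node.bwd(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents, bwd) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out.parents = tuple(parents)
        out.bwd = bwd
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -------------------------------------------------------------- elementwise

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(x.data * mask, (x,), lambda g: (g * mask,))


def leaky_relu(x: Tensor, alpha: float = 0.05) -> Tensor:
    """Leaky rectifier; the small negative slope avoids dead units under
    the large learning rates the training schedules use."""
    coef = np.where(x.data > 0, 1.0, alpha).astype(np.float32)
    return _make(x.data * coef, (x,), lambda g: (g * coef,))


def reshape(x: Tensor, shape) -> Tensor:
    old = x.shape
    return _make(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def channel_slice(x: Tensor, c0: int, c1: int) -> Tensor:
    """Slice channels of an (N, C, H, W) tensor."""

    def bwd(g):
        full = np.zeros_like(x.data)
        full[:, c0:c1] = g
        return (full,)

    return _make(x.data[:, c0:c1], (x,), bwd)


# -------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (N, C, k, k, H, W), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(view).reshape(N, C * k * k, H * W)


def _col2im(dcols: np.ndarray, xshape, k: int, pad: int) -> np.ndarray:
    N, C, H, W = xshape
    d = dcols.reshape(N, C, k, k, H, W)
    out = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + H, j : j + W] += d[:, :, i, j]
    return out[:, :, pad : pad + H, pad : pad + W]


def conv2d(x: Tensor, w: Tensor, b: Tensor, k: int) -> Tensor:
    """Same-padded stride-1 convolution.

    ``w`` has shape (C_out, C_in * k * k) and ``b`` (C_out,).
    """
    N, C, H, W = x.shape
    pad = k // 2
    cols = _im2col(x.data, k, pad)  # (N, C*k*k, H*W)
    y = np.matmul(w.data, cols) + b.data[None, :, None]
    y = y.reshape(N, w.shape[0], H, W)

    def bwd(g):
        gf = g.reshape(N, w.shape[0], H * W)
        dw = np.einsum("ncl,nkl->ck", gf, cols, optimize=True)
        db = gf.sum(axis=(0, 2))
        dcols = np.matmul(w.data.T, gf)
        dx = _col2im(dcols, x.shape, k, pad)
        return dx, dw, db

    return _make(y, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]

    def bwd(g):
        ge = g[:, :, :, None, :, None] * mask
        return (ge.reshape(N, C, H // 2 * 2, W // 2 * 2),)

    return _make(y, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        return (g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return _make(y, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    y = x.data.mean(axis=(2, 3))

    def bwd(g):
        return (np.broadcast_to(g[:, :, None, None] / (H * W), x.shape).copy(),)

    return _make(y, (x,), bwd)


def l2_normalize_rows(x: Tensor, eps: float = 1e-8) -> Tensor:
    n = np.sqrt((x.data**2).sum(axis=1, keepdims=True)) + eps
    y = x.data / n

    def bwd(g):
        dot = (g * y).sum(axis=1, keepdims=True)
        return ((g - y * dot) / n,)

    return _make(y, (x,), bwd)


def affine_channels(x: Tensor, s: Tensor) -> Tensor:
    """Add a per-sample per-channel bias: x (N,C,H,W) + s (N,C)."""
    y = x.data + s.data[:, :, None, None]

    def bwd(g):
        return g, g.sum(axis=(2, 3))

    return _make(y, (x, s), bwd)


# -------------------------------------------------------------- batch norm

def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Training-mode batch normalisation over (N, H, W) per channel.

    Returns ``(y, batch_mean, batch_var)``; the caller is responsible for
    maintaining running statistics for evaluation mode.
    """
    axes = (0, 2, 3)
    m = x.data.size // x.shape[1]
    mu = x.data.mean(axis=axes)
    var = x.data.var(axis=axes)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        gx = g * gamma.data[None, :, None, None]
        mean_gx = gx.mean(axis=axes)
        mean_gx_xhat = (gx * xhat).mean(axis=axes)
        dx = (
            gx
            - mean_gx[None, :, None, None]
            - xhat * mean_gx_xhat[None, :, None, None]
        ) / std[None, :, None, None]
        return dx, dgamma, dbeta

    out = _make(y, (x, gamma, beta), bwd)
    return out, mu, var, m


# -------------------------------------------------------------- losses

def mean_square(x: Tensor) -> Tensor:
    n = x.data.size

    def bwd(g):
        return (g * 2.0 * x.data / n,)

    return _make(np.array(np.mean(x.data**2), dtype=np.float32), (x,), bwd)


def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    t = np.asarray(target, dtype=np.float32)
    zd = z.data
    loss = np.mean(np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd))))
    n = zd.size

    def bwd(g):
        sig = 1.0 / (1.0 + np.exp(-zd))
        return (g * (sig - t) / n,)

    return _make(np.array(loss, dtype=np.float32), (z,), bwd)
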