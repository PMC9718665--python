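"""Layers and the SGD optimizer for the numpy U-net."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Param", "Conv2d", "BatchNorm2d", "Linear", "ResBlock", "SGD"]


class Param(Tensor):
    """A trainable tensor. ``decay`` marks it for weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, name: str = "", decay: bool = True):
        super().__init__(data, requires_grad=True, name=name)
        self.decay = decay


class Module:
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        out: dict[str, np.ndarray] = {}
        for k, v in vars(self).items():
            key = f"{prefix}{k}"
            if isinstance(v, Param):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in vars(self).items():
            key = f"{prefix}{k}"
            if isinstance(v, Param):
                v.data = np.ascontiguousarray(state[key], dtype=np.float32)
            elif isinstance(v, np.ndarray):
                setattr(self, k, np.asarray(state[key]))
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.w = Param(w, name=f"conv{k}x{k}.w")
        self.b = Param(np.zeros(c_out), name="conv.b", decay=False)
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, self.k)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), name="bn.gamma", decay=False)
        self.beta = Param(np.zeros(c), name="bn.beta", decay=False)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            y, mu, var, m = ag.batchnorm_train(x, self.gamma, self.beta, self.eps)
            unbias = m / max(m - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var * unbias
            ).astype(np.float32)
            return y
        std = np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data / std
        shift = self.beta.data - self.running_mean * scale
        # eval mode is a fixed per-channel affine map
        y = x.data * scale[None, :, None, None] + shift[None, :, None, None]
        out = ag.Tensor(y)
        if x.requires_grad or self.gamma.requires_grad:
            out.requires_grad = True
            out.parents = (x, self.gamma, self.beta)
            xhat = (x.data - self.running_mean[None, :, None, None]) / std[
                None, :, None, None
            ]
            out.bwd = lambda g: (
                g * scale[None, :, None, None],
                (g * xhat).sum(axis=(0, 2, 3)),
                g.sum(axis=(0, 2, 3)),
            )
        return out


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float | None = None):
        s = scale if scale is not None else np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, s, size=(d_in, d_out)), name="linear.w")
        self.b = Param(np.zeros(d_out), name="linear.b", decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.w), self.b)


class ResBlock(Module):
    """conv-bn-lrelu-conv-bn with an (optionally projected) skip, then lrelu."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        y = ag.leaky_relu(self.bn1(self.conv1(x), train))
        y = self.bn2(self.conv2(y), train)
        skip = self.proj(x) if self.proj is not None else x
        return ag.leaky_relu(ag.add(y, skip))


class SGD:
    """SGD with momentum, weight decay and global gradient-norm clipping."""

    def __init__(
        self,
        params: list[Param],
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        max_grad_norm: float | None = None,
    ):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(
                sum(
                    float((p.grad**2).sum())
                    for p in self.params
                    if p.grad is not None
                )
            )
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v
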