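"""Neural-network building blocks on top of :mod:`stecg.nn.autograd`.

Covers exactly what the hybrid time-frequency classifier needs: convolution,
batch/layer normalisation, linear layers, dropout, per-sample stochastic
depth, and a post-norm Transformer encoder block.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, maxpool2d, softmax


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal -------------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for c in self.children():
            yield from c.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def visit(mod: "Module", prefix: str):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out.append((f"{prefix}{k}", v))
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")
        visit(self, "")
        return out

    # -- modes -----------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.array(value, dtype=params[name].data.dtype)
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _named_buffers(self) -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []

        def visit(mod: "Module", prefix: str):
            for k in getattr(mod, "_buffers", ()):
                out.append((f"{prefix}{k}", getattr(mod, k)))
            for k, v in mod.__dict__.items():
                if isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")
        visit(self, "")
        return out

    def seed_rng(self, seed: int):
        """Give every stochastic submodule one shared, freshly seeded RNG."""
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, (Dropout, DropPath)):
                m.rng = rng
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int, kind: str = "kaiming") -> Tensor:
    if kind == "kaiming":
        std = math.sqrt(2.0 / fan_in)
        data = rng.normal(0.0, std, size=shape)
    elif kind == "uniform":
        bound = 1.0 / math.sqrt(fan_in)
        data = rng.uniform(-bound, bound, size=shape)
    else:
        raise ValueError(kind)
    return Tensor(data.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, kernel, stride=1, groups=1, bias=True):
        super().__init__()
        self.stride = (stride, stride) if np.isscalar(stride) else tuple(stride)
        k = (kernel, kernel) if np.isscalar(kernel) else tuple(kernel)
        self.padding = (k[0] // 2, k[1] // 2)  # "same"-style: out = ceil(in/stride)
        self.groups = groups
        fan_in = (in_ch // groups) * k[0] * k[1]
        self.weight = _param(rng, (out_ch, in_ch // groups, k[0], k[1]), fan_in)
        self.bias = _param(rng, (out_ch,), fan_in, "uniform") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, n_ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones((1, n_ch, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_ch, 1, 1), np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, n_ch, 1, 1), np.float32)
        self.running_var = np.ones((1, n_ch, 1, 1), np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import batchnorm2d

        out, mu, var = batchnorm2d(x, self.gamma, self.beta,
                                   self.running_mean, self.running_var,
                                   self.eps, self.training)
        if self.training:
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.astype(np.float32))
        return out


class Linear(Module):
    def __init__(self, rng, in_f, out_f, bias=True):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = _param(rng, (in_f, out_f), in_f, "uniform")
        self.bias = _param(rng, (out_f,), in_f, "uniform") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        y = x.reshape(-1, self.in_f) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y.reshape(*lead, self.out_f)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((dim,), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((dim,), np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p=0.2):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1 - self.p)
        return x * Tensor(mask)


class DropPath(Module):
    """Stochastic depth: drop a residual branch per sample during training.

    Kept branches are rescaled by 1/(1-p) so the expectation matches; at
    eval the branch passes through untouched (exact identity behaviour).
    """

    def __init__(self, p=0.2):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, branch: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return branch
        rng = self.rng if self.rng is not None else np.random.default_rng()
        B = branch.shape[0]
        keep = (rng.random(B) >= self.p).astype(branch.data.dtype) / (1 - self.p)
        keep = keep.reshape((B,) + (1,) * (branch.ndim - 1))
        return branch * Tensor(keep)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, dim, n_heads, dropout=0.2):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embed dim must be divisible by the head count")
        self.dim, self.h = dim, n_heads
        self.dh = dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)
        self.attn_drop = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))
        attn = self.attn_drop(softmax(scores, axis=-1))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.wo(out)


class TransformerBlock(Module):
    """Post-norm encoder block: MHSA and position-wise FFN, each with a
    residual connection followed by layer normalisation."""

    def __init__(self, rng, dim, n_heads, ffn_dim, dropout=0.2):
        super().__init__()
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads, dropout)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(rng, dim, ffn_dim)
        self.fc2 = Linear(rng, ffn_dim, dim)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)
        self.drop_ffn = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x)))
        ffn = self.fc2(self.drop_ffn(self.fc1(x).relu()))
        return self.ln2(x + self.drop2(ffn))
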