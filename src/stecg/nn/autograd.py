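"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's classifier is trained on CPU with plain numpy; this module
provides the small set of differentiable primitives the architecture needs
(broadcast arithmetic, matmul, reductions, conv2d/maxpool2d via im2col,
softmax building blocks).  Gradients are checked against central finite
differences in the test suite.

Conventions
-----------
* ``Tensor.data`` is always a numpy array; dtype is whatever numpy promotion
  yields (parameters are float32, oracle tests may use float64).
* ``backward()`` accumulates into ``Tensor.grad`` (a numpy array), using a
  topological sort of the recorded graph.
* A module-level switch (:func:`no_grad`) disables graph recording for
  inference loops.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._children: tuple = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
        # out-of-place accumulation: incoming grads may alias upstream buffers
        self.grad = g if self.grad is None else self.grad + g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for ch in node._children:
                if id(ch) not in seen:
                    stack.append((ch, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if node._children:
                # Interior node: free its gradient and break the closure
                # cycle (closure captures the node) so memory is reclaimed
                # by reference counting, not the cyclic GC.  Only leaves
                # (parameters, inputs) keep their grads.
                node.grad = None
                node._backward = None
                node._children = ()

    # ------------------------------------------------------------- helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data, children: Sequence["Tensor"], backward_factory):
        out = Tensor(data)
        if _GRAD_ENABLED and any(c.requires_grad for c in children):
            out.requires_grad = True
            out._children = tuple(children)
            out._backward = backward_factory(out)
        return out

    # ------------------------------------------------------------ arithmetic
    # Python scalars take a dedicated path so that numpy's weak-scalar
    # promotion applies (a float32 graph stays float32 throughout).
    def _scalar_op(self, c: float, data: np.ndarray, gfun):
        a = self

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(gfun(out.grad, c))
            return _b

        return Tensor._make(data, (a,), bw)

    def __add__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self._scalar_op(other, self.data + other, lambda g, c: g)
        a, b = self, Tensor._lift(other)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad)
                if b.requires_grad:
                    b._accum(out.grad)
            return _b

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(-out.grad)
            return _b

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self._scalar_op(other, other - self.data, lambda g, c: -g)
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self._scalar_op(other, self.data * other,
                                   lambda g, c: g * c)
        a, b = self, Tensor._lift(other)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * b.data)
                if b.requires_grad:
                    b._accum(out.grad * a.data)
            return _b

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self * (1.0 / other)
        a, b = self, Tensor._lift(other)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad / b.data)
                if b.requires_grad:
                    b._accum(-out.grad * a.data / (b.data * b.data))
            return _b

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, c: float):
        if not np.isscalar(c):
            raise TypeError("only scalar exponents are supported")
        a = self

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * c * a.data ** (c - 1))
            return _b

        return Tensor._make(a.data ** c, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(np.matmul(out.grad, np.swapaxes(b.data, -1, -2)))
                if b.requires_grad:
                    b._accum(np.matmul(np.swapaxes(a.data, -1, -2), out.grad))
            return _b

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # ------------------------------------------------------------- unary ops
    def exp(self):
        a = self
        data = np.exp(a.data)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * out.data)
            return _b

        return Tensor._make(data, (a,), bw)

    def log(self):
        a = self

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad / a.data)
            return _b

        return Tensor._make(np.log(a.data), (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * mask)
            return _b

        return Tensor._make(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * out.data * (1.0 - out.data))
            return _b

        return Tensor._make(s, (a,), bw)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * (1.0 - out.data ** 2))
            return _b

        return Tensor._make(t, (a,), bw)

    def clip_min(self, lo: float):
        """Elementwise max(x, lo); gradient passes only where x > lo."""
        a = self
        mask = a.data > lo

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad * mask)
            return _b

        return Tensor._make(np.maximum(a.data, lo), (a,), bw)

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad.reshape(a.data.shape))
            return _b

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(out):
            def _b():
                if a.requires_grad:
                    a._accum(out.grad.transpose(inv))
            return _b

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(out):
            def _b():
                if a.requires_grad:
                    g = np.zeros_like(a.data)
                    np.add.at(g, idx, out.grad)
                    a._accum(g)
            return _b

        return Tensor._make(a.data[idx], (a,), bw)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(out):
            def _b():
                if not a.requires_grad:
                    return
                g = out.grad
                if axis is not None and not keepdims:
                    axes = (axis,) if np.isscalar(axis) else tuple(axis)
                    g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
                a._accum(np.broadcast_to(g, a.data.shape))
            return _b

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ------------------------------------------------------------------ functional


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``t[i, idx[i]]`` for each row i of a 2-D tensor."""
    idx = np.asarray(idx)
    rows = np.arange(t.data.shape[0])

    def bw(out):
        def _b():
            if t.requires_grad:
                g = np.zeros_like(t.data)
                np.add.at(g, (rows, idx), out.grad)
                t._accum(g)
        return _b

    return Tensor._make(t.data[rows, idx], (t,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


# --------------------------------------------------------------- convolution

_COL_CHUNK_FLOATS = 16_000_000  # cap im2col scratch at ~64 MB of float32


def _conv_geometry(H, W, kh, kw, sh, sw, ph, pw):
    OH = (H + 2 * ph - kh) // sh + 1
    OW = (W + 2 * pw - kw) // sw + 1
    return OH, OW


def _im2col(xp: np.ndarray, kh, kw, sh, sw, OH, OW) -> np.ndarray:
    """[B,C,Hp,Wp] -> [B, OH*OW, C*kh*kw] (copy)."""
    from numpy.lib.stride_tricks import sliding_window_view

    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    # v: [B, C, OH, OW, kh, kw] -> [B, OH, OW, C, kh, kw]
    v = v.transpose(0, 2, 3, 1, 4, 5)
    B = xp.shape[0]
    C = xp.shape[1]
    return np.ascontiguousarray(v).reshape(B, OH * OW, C * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1), padding=(0, 0),
           groups: int = 1) -> Tensor:
    """2-D cross-correlation with groups, stride and zero padding.

    x: [B, C, H, W]; w: [Cout, C//groups, kh, kw]; b: [Cout] or None.
    Spatial output sizes follow ceil(H/stride) when padding = kernel//2
    (odd kernels), matching the network's shape contract.
    """
    B, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    sh, sw = stride
    ph, pw = padding
    G = groups
    if C != Cg * G or Cout % G:
        raise ValueError("channel/group mismatch in conv2d")
    OH, OW = _conv_geometry(H, W, kh, kw, sh, sw, ph, pw)
    Og = Cout // G

    if kh == kw == 1 and G == 1:
        return _conv1x1(x, w, b, sh, sw, OH, OW)

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.empty((B, Cout, OH, OW), dtype=np.result_type(x.data, w.data))
    wmat = w.data.reshape(G, Og, Cg * kh * kw)

    chunk = max(1, _COL_CHUNK_FLOATS // max(1, OH * OW * C * kh * kw))
    for s in range(0, B, chunk):
        e = min(B, s + chunk)
        cols = _im2col(xp[s:e], kh, kw, sh, sw, OH, OW)  # [b, P, C*kh*kw]
        cols = cols.reshape(e - s, OH * OW, G, Cg * kh * kw)
        for g in range(G):
            # [b, P, K] @ [K, Og] -> [b, P, Og]
            o = cols[:, :, g] @ wmat[g].T
            out[s:e, g * Og:(g + 1) * Og] = o.transpose(0, 2, 1).reshape(
                e - s, Og, OH, OW)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)

    children = (x, w) if b is None else (x, w, b)

    def bw(outT):
        def _b():
            go = outT.grad  # [B, Cout, OH, OW]
            if b is not None and b.requires_grad:
                b._accum(go.sum(axis=(0, 2, 3)))
            need_x = x.requires_grad
            need_w = w.requires_grad
            if not (need_x or need_w):
                return
            gw = np.zeros_like(w.data) if need_w else None
            gxp = np.zeros_like(xp) if need_x else None
            for s in range(0, B, chunk):
                e = min(B, s + chunk)
                cols = _im2col(xp[s:e], kh, kw, sh, sw, OH, OW)
                cols = cols.reshape(e - s, OH * OW, G, Cg * kh * kw)
                gos = go[s:e].reshape(e - s, G, Og, OH * OW)
                for g in range(G):
                    gog = gos[:, g]  # [b, Og, P]
                    if need_w:
                        # sum_b [Og, P] @ [P, K]
                        gw_g = np.einsum("bop,bpk->ok", gog, cols[:, :, g],
                                         optimize=True)
                        gw[g * Og:(g + 1) * Og] += gw_g.reshape(Og, Cg, kh, kw)
                    if need_x:
                        # [b, P, K] = [b, P, Og] @ [Og, K]
                        gcols = np.matmul(gog.transpose(0, 2, 1), wmat[g])
                        gcols = gcols.reshape(e - s, OH, OW, Cg, kh, kw)
                        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)
                        # scatter back: loop over kernel taps (vectorised adds)
                        c0 = g * Cg
                        for i in range(kh):
                            for j in range(kw):
                                gxp[s:e, c0:c0 + Cg,
                                    i:i + OH * sh:sh,
                                    j:j + OW * sw:sw] += gcols[..., i, j]
            if need_w:
                w._accum(gw)
            if need_x:
                if ph or pw:
                    x._accum(gxp[:, :, ph:ph + H, pw:pw + W])
                else:
                    x._accum(gxp)
        return _b

    return Tensor._make(out, children, bw)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, sh: int, sw: int,
             OH: int, OW: int) -> Tensor:
    """Pointwise convolution as a single batched matmul (no im2col)."""
    B, C = x.data.shape[:2]
    Cout = w.data.shape[0]
    xs = x.data[:, :, ::sh, ::sw] if (sh > 1 or sw > 1) else x.data
    xsr = np.ascontiguousarray(xs).reshape(B, C, OH * OW)
    w2 = w.data.reshape(Cout, C)
    out = np.matmul(w2, xsr).reshape(B, Cout, OH, OW)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)
    children = (x, w) if b is None else (x, w, b)

    def bw(outT):
        def _b():
            g = outT.grad.reshape(B, Cout, OH * OW)
            if b is not None and b.requires_grad:
                b._accum(outT.grad.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.einsum("bop,bcp->oc", g, xsr, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gxs = np.matmul(w2.T, g).reshape(B, C, OH, OW)
                if sh > 1 or sw > 1:
                    gx = np.zeros_like(x.data)
                    gx[:, :, ::sh, ::sw] = gxs
                    x._accum(gx)
                else:
                    x._accum(gxs)
        return _b

    return Tensor._make(out, children, bw)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling; padded cells are -inf and can never win.

    Computed as a running elementwise maximum over the k*k kernel taps, so no
    window copy of the input is ever materialised; ties route the gradient to
    the first winning tap in scan order.
    """
    B, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    OH, OW = _conv_geometry(H, W, k, k, s, s, p, p)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf)
    out = np.full((B, C, OH, OW), -np.inf, dtype=x.data.dtype)
    for t in range(k * k):
        i, j = divmod(t, k)
        np.maximum(out, xp[:, :, i:i + OH * s:s, j:j + OW * s:s], out=out)

    def bw(outT):
        def _b():
            if not x.requires_grad:
                return
            gxp = np.zeros_like(xp, dtype=outT.grad.dtype)
            used = np.zeros((B, C, OH, OW), dtype=bool)
            for t in range(k * k):
                i, j = divmod(t, k)
                sub = xp[:, :, i:i + OH * s:s, j:j + OW * s:s]
                mask = (sub == out) & ~used
                used |= mask
                gxp[:, :, i:i + OH * s:s, j:j + OW * s:s] += outT.grad * mask
            x._accum(gxp[:, :, p:p + H, p:p + W])
        return _b

    return Tensor._make(out, (x,), bw)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
                var: np.ndarray, eps: float, training: bool):
    """Fused batch normalisation over (batch, H, W) per channel.

    In training mode the batch statistics are computed internally (returned
    so the caller can update running estimates) and the full backward through
    mean and variance is applied; in eval mode ``mean``/``var`` are treated
    as constants.  Fused so the graph retains one normalised copy of the
    activation instead of a chain of intermediates.
    """
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mean) / std
    out_data = gamma.data * xhat + beta.data

    def bw(outT):
        def _b():
            g = outT.grad
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes, keepdims=True))
            if x.requires_grad:
                if training:
                    gm = g.mean(axis=axes, keepdims=True)
                    gxm = (g * xhat).mean(axis=axes, keepdims=True)
                    x._accum((gamma.data / std) * (g - gm - xhat * gxm))
                else:
                    x._accum(g * gamma.data / std)
        return _b

    out = Tensor._make(out_data, (x, gamma, beta), bw)
    return out, mean, var
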