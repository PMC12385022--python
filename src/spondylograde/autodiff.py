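"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supplies exactly the primitives the segmentation network needs: broadcasted
elementwise arithmetic, matmul, 2-D convolution (stride 1, 'same' or 'valid'),
2x2/stride-2 transpose convolution, 2x2 max-pooling, batch normalisation,
channel concatenation, reductions, and class-probability gathering. Gradients
are accumulated on a dynamically recorded tape and released after ``backward``.

All tensors are NCHW (batch, channel, height, width) where spatial layout
matters. Default dtype is float32; float64 is supported for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "maxpool2x2", "batchnorm2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad += g

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free the tape as we go; parameters keep their grads
                t._parents = ()
                t._backward = None

    # -- elementwise ----------------------------------------------------------
    def _coerce(self, other):
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def clamp_min(self, lo: float):
        mask = self.data > lo

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), bwd)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        out_data = self.data @ other.data

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bwd)

    __matmul__ = matmul

    def log_softmax(self, axis: int):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bwd(g):
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), bwd)

    def gather_class(self, labels: np.ndarray, axis: int = 1):
        """Select, per position, the entry of `axis` given by integer `labels`.

        For NKHW input with NHW labels returns NHW values (the per-pixel score
        of each pixel's true class).
        """
        labels = np.asarray(labels)
        idx = np.expand_dims(labels, axis)
        out_data = np.take_along_axis(self.data, idx, axis=axis).squeeze(axis)
        shape = self.shape

        def bwd(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.put_along_axis(full, idx, np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    def take_points(self, rows: np.ndarray, cols: np.ndarray):
        """Sample NCHW features at (rows, cols) per batch item -> (N, P, C)."""
        n = self.shape[0]
        out_data = self.data[:, :, rows, cols].transpose(0, 2, 1)
        shape = self.shape

        def bwd(g):
            full = np.zeros(shape, dtype=g.dtype)
            for b in range(n):
                np.add.at(full[b].transpose(1, 2, 0), (rows, cols), g[b])
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# Convolution primitives (NCHW, stride 1, odd square kernels, 'same' padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for a stride-1 convolution."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


def _conv_raw(x: np.ndarray, weight: np.ndarray, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    co, ci, k, _ = weight.shape
    cols = _im2col(x, k, pad)
    out = cols @ weight.reshape(co, ci * k * k).T
    return out.reshape(n, h, w, co).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same' convolution. weight: (C_out, C_in, k, k), k odd."""
    co, ci, k, _ = weight.shape
    pad = k // 2
    out_data, cols = _conv_raw(x.data, weight.data, pad)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)
    n, _, h, w = out_data.shape

    def bwd(g):
        g_mat = g.transpose(0, 2, 3, 1).reshape(n * h * w, co)
        weight._accum((g_mat.T @ cols).reshape(weight.shape))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dx, _ = _conv_raw(g, np.ascontiguousarray(w_flip), pad)
            x._accum(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, bwd)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2 kernel, stride-2 transpose convolution (exact x2 upsampling).

    weight: (C_in, C_out, 2, 2). Because kernel size equals stride, output
    windows do not overlap and the operation is a per-pixel linear map.
    """
    n, ci, h, w = x.shape
    _, co, k, _ = weight.shape
    t = np.einsum("ncij,cokl->noikjl", x.data, weight.data, optimize=True)
    out_data = t.reshape(n, co, h * k, w * k)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)

    def bwd(g):
        g6 = g.reshape(n, co, h, k, w, k)
        weight._accum(np.einsum("ncij,noikjl->cokl", x.data, g6, optimize=True))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.einsum("noikjl,cokl->ncij", g6, weight.data, optimize=True))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {(h, w)}")
    h2, w2 = h // 2, w // 2
    patches = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = patches.argmax(axis=-1)
    out_data = np.take_along_axis(patches, idx[..., None], axis=-1).squeeze(-1)

    def bwd(g):
        scattered = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(scattered, idx[..., None], g[..., None], axis=-1)
        dx = scattered.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(dx)

    return Tensor._make(out_data, (x,), bwd)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    `running` holds 'mean' and 'var' arrays updated in training mode and used
    verbatim in eval mode.
    """
    c = x.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gshape)) * invstd.reshape(gshape)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def bwd(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        dxhat = g * gamma.data.reshape(gshape)
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
            x._accum(term * invstd.reshape(gshape))
        else:
            x._accum(dxhat * invstd.reshape(gshape))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


class Adam:
    """Adam optimiser with optional decoupled L2 penalty."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, l2_weight=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.l2 = lr, betas, eps, l2_weight
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2:
                g = g + self.l2 * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
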