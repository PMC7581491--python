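"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations needed by the segmentation network:
broadcast arithmetic, matmul, activations, reductions, channel softmax,
``same``-padded 2-D convolution (via im2col + BLAS), 2x2 stride-2
transposed convolution, 2x2 max pooling, batch normalization, dropout
and channel concatenation.  All tensors are float32; layout is NCHW.

Gradients are accumulated by topological traversal of the recorded
graph.  A module-level switch (:class:`no_grad`) disables graph
recording during validation/inference.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        rec = _GRAD_ENABLED and (requires_grad or any(p.requires_grad for p in parents))
        self.requires_grad = rec
        self._parents = tuple(parents) if rec else ()
        self._backward = backward if rec else None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def _accum_slice(self, g, di, dj):
        """Accumulate into grad[:, :, di, dj] (4-D conv-weight gradients)."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[:, :, di, dj] += g

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == tuple(shape):
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ----------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def sub(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def div(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def maximum(a, b):
    """Element-wise maximum; ties split the gradient equally."""
    a, b = astensor(a), astensor(b)
    out_data = np.maximum(a.data, b.data)

    def bwd(g):
        gt = a.data > b.data
        lt = a.data < b.data
        eq = ~(gt | lt)
        if a.requires_grad:
            a._accum(_unbroadcast(g * (gt + 0.5 * eq), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (lt + 0.5 * eq), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


# -- activations ---------------------------------------------------------

def relu(x):
    x = astensor(x)
    out_data = np.maximum(x.data, 0.0)

    def bwd(g):
        x._accum(g * (x.data > 0))

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x):
    x = astensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax(x, axis=1):
    """Softmax along ``axis`` with a numerically stable shift."""
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor(out_data, parents=(x,), backward=bwd)


# -- reductions & shaping -------------------------------------------------

def tsum(x, axis=None, keepdims=False):
    x = astensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            x._accum(np.broadcast_to(g, x.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            x._accum(np.broadcast_to(g, x.data.shape))

    return Tensor(out_data, parents=(x,), backward=bwd)


def tmean(x, axis=None, keepdims=False):
    x = astensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(x, shape):
    x = astensor(x)
    out_data = x.data.reshape(shape)

    def bwd(g):
        x._accum(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=bwd)


def concat(tensors, axis=1):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# -- convolution (NCHW, stride 1, "same" padding) --------------------------

def conv2d(x, w, b):
    """Same-padded stride-1 convolution; ``w``: (Cout, Cin, k, k), ``b``: (Cout,).

    Computed as k*k shifted GEMMs over the zero-padded input, which
    avoids materializing the full im2col patch matrix.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    N, C, H, W = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    p = k // 2
    if k == 1:
        xm = x.data.reshape(N, C, H * W)
        out_data = (np.matmul(w.data.reshape(Cout, C), xm)
                    + b.data[:, None]).reshape(N, Cout, H, W)

        def bwd1(g):
            gmat = g.reshape(N, Cout, H * W)
            if w.requires_grad:
                dw = np.matmul(gmat, xm.transpose(0, 2, 1)).sum(axis=0)
                w._accum(dw.reshape(w.data.shape))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(np.matmul(w.data.reshape(Cout, C).T, gmat)
                         .reshape(x.data.shape))

        return Tensor(out_data, parents=(x, w, b), backward=bwd1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((N, Cout, H * W), dtype=np.float32)
    buf = np.empty((N, C, H, W), dtype=np.float32)
    for di in range(k):
        for dj in range(k):
            np.copyto(buf, xp[:, :, di:di + H, dj:dj + W])
            out += np.matmul(w.data[:, :, di, dj], buf.reshape(N, C, H * W))
    out_data = (out + b.data[:, None]).reshape(N, Cout, H, W)

    def bwd(g):
        gmat = g.reshape(N, Cout, H * W)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad
        gxp = (np.zeros_like(xp) if need_dx else None)
        sbuf = np.empty((N, C, H, W), dtype=np.float32)
        gmatT = np.ascontiguousarray(gmat.transpose(0, 2, 1)) if w.requires_grad else None
        for di in range(k):
            for dj in range(k):
                if w.requires_grad:
                    np.copyto(sbuf, xp[:, :, di:di + H, dj:dj + W])
                    dwT = np.matmul(sbuf.reshape(N, C, H * W), gmatT).sum(axis=0)
                    w._accum_slice(dwT.T, di, dj)
                if need_dx:
                    dxs = np.matmul(w.data[:, :, di, dj].T, gmat)
                    gxp[:, :, di:di + H, dj:dj + W] += dxs.reshape(N, C, H, W)
        if need_dx:
            x._accum(gxp[:, :, p:p + H, p:p + W])

    return Tensor(out_data, parents=(x, w, b), backward=bwd)


def conv_transpose2x2(x, w, b):
    """2x2 stride-2 transposed convolution (non-overlapping upsampling).

    ``w``: (Cin, Cout, 2, 2); output spatial size is doubled.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    N, C, H, W = x.data.shape
    Cin, Cout = w.data.shape[:2]
    if Cin != C:
        raise ValueError(f"conv_transpose2x2: {C} channels vs weight {Cin}")
    wm = w.data.reshape(Cin, Cout * 4)
    out4 = np.matmul(wm.T, x.data.reshape(N, C, H * W))  # (N, Cout*4, H*W)
    out = (
        out4.reshape(N, Cout, 2, 2, H, W)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(N, Cout, 2 * H, 2 * W)
    )
    out += b.data[:, None, None]

    def bwd(g):
        g4 = (
            g.reshape(N, Cout, H, 2, W, 2)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(N, Cout * 4, H * W)
        )
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.matmul(g4, x.data.reshape(N, C, H * W).transpose(0, 2, 1)).sum(0)
            w._accum(dw.T.reshape(w.data.shape))
        if x.requires_grad:
            x._accum(np.matmul(wm, g4).reshape(x.data.shape))

    return Tensor(out, parents=(x, w, b), backward=bwd)


def maxpool2x2(x):
    """2x2 stride-2 max pooling; spatial dims must be even."""
    x = astensor(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    H2, W2 = H // 2, W // 2
    x4 = x.data.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H2, W2, 4
    )
    arg = x4.argmax(axis=-1)
    out_data = np.take_along_axis(x4, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        g4 = np.zeros((N, C, H2, W2, 4), dtype=np.float32)
        np.put_along_axis(g4, arg[..., None], g[..., None], axis=-1)
        gx = g4.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H, W
        )
        x._accum(gx)

    return Tensor(out_data, parents=(x,), backward=bwd)


# -- normalization & regularization ----------------------------------------

def batchnorm2d(x, gamma, beta, running_mean, running_var, training,
                momentum=0.1, eps=1e-5):
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain float32 arrays updated in
    place during training and used verbatim at inference.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    if training:
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        m = x.data.mean(axis=(0, 2, 3))
        v = np.einsum("nchw,nchw->c", x.data, x.data) / n - m * m
        np.maximum(v, 0.0, out=v)
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    ivstd = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[:, None, None]) * ivstd[:, None, None]
    out_data = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[:, None, None]
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_gs = gs.sum(axis=(0, 2, 3))
                sum_gs_xhat = (gs * xhat).sum(axis=(0, 2, 3))
                dx = (
                    gs
                    - (sum_gs / n)[:, None, None]
                    - xhat * (sum_gs_xhat / n)[:, None, None]
                ) * ivstd[:, None, None]
                x._accum(dx)
            else:
                x._accum(gs * ivstd[:, None, None])

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


def dropout(x, p, rng, training):
    """Inverted dropout with keep-probability ``1-p``."""
    x = astensor(x)
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return mul(x, mask)
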