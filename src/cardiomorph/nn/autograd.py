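"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tensor algebra to train the small convolutional networks in this
package on a CPU: broadcasting elementwise ops, matmul, reshape/concat,
2D convolution (stride 1, zero padding), 2x2 max-pool / average-pool /
nearest-neighbour upsampling, and a fused softmax cross-entropy. float32
throughout. Not a general framework and not meant to be one.
"""
from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = _wrap(a)
    return _make(-a.data, (a,), lambda g: a._accumulate(-g))


def sub(a, b):
    return add(a, neg(b))


def pow_const(a, p: float):
    a = _wrap(a)
    out_data = a.data**p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = _wrap(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * np.where(mask, 1.0, slope).astype(np.float32))

    return _make(np.where(mask, a.data, slope * a.data), (a,), backward)


def softplus(a):
    a = _wrap(a)
    out_data = np.logaddexp(0.0, a.data).astype(np.float32)

    def backward(g):
        a._accumulate(g / (1.0 + np.exp(-a.data)))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# shape / reduction


def reshape(a, shape):
    a = _wrap(a)
    orig = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int = 0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def tsum(a, axis=None, keepdims: bool = False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# 2D image ops (NCHW)


def conv2d(x, w, b=None, padding: str = "same"):
    """2D convolution, stride 1; ``w`` has shape (Cout, Cin, kh, kw)."""
    x, w = _wrap(x), _wrap(w)
    B, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    assert Cin == C, f"channel mismatch: input {C}, kernel {Cin}"
    if padding == "same":
        ph, pw = kh // 2, kw // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    # im2col: (B, Ho, Wo, C*kh*kw)
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(Cout, C * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        b = _wrap(b)
        out = out + b.data.reshape(1, Cout)
    out_data = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Cout)
        w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(gmat.sum(axis=0).reshape(b.data.shape))
        gcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if ph or pw:
            gx = gxp[:, :, ph : ph + H, pw : pw + W]
        else:
            gx = gxp
        x._accumulate(gx)

    return _make(out_data, parents, backward)


def maxpool2d(x, size: int = 2):
    x = _wrap(x)
    B, C, H, W = x.data.shape
    assert H % size == 0 and W % size == 0, "spatial dims must divide pool size"
    r = x.data.reshape(B, C, H // size, size, W // size, size)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]

    def backward(g):
        gexp = np.broadcast_to(g[:, :, :, None, :, None], r.shape) * mask
        x._accumulate(gexp.reshape(B, C, H, W).astype(np.float32))

    return _make(out_data, (x,), backward)


def avgpool2d(x, size: int = 2):
    x = _wrap(x)
    B, C, H, W = x.data.shape
    r = x.data.reshape(B, C, H // size, size, W // size, size)
    out_data = r.mean(axis=(3, 5))
    inv = 1.0 / (size * size)

    def backward(g):
        gexp = np.broadcast_to(g[:, :, :, None, :, None] * inv, r.shape)
        x._accumulate(gexp.reshape(B, C, H, W).astype(np.float32))

    return _make(out_data, (x,), backward)


def upsample2d(x, size: int = 2):
    """Nearest-neighbour upsampling by an integer factor."""
    x = _wrap(x)
    B, C, H, W = x.data.shape
    out_data = x.data.repeat(size, axis=2).repeat(size, axis=3)

    def backward(g):
        gr = g.reshape(B, C, H, size, W, size).sum(axis=(3, 5))
        x._accumulate(gr)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# losses


def softmax_cross_entropy(logits, targets: np.ndarray, class_weights=None):
    """Mean cross-entropy of NCHW logits (or (B, N) logits) against integer
    targets; fused and numerically stabilized."""
    logits = _wrap(logits)
    ld = logits.data
    if ld.ndim == 4:
        B, N, H, W = ld.shape
        flat = ld.transpose(0, 2, 3, 1).reshape(-1, N)
        t = np.asarray(targets).reshape(-1)
    else:
        flat = ld
        N = flat.shape[1]
        t = np.asarray(targets).reshape(-1)
    shifted = flat - flat.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1))
    logp = shifted - lse[:, None]
    if class_weights is None:
        wv = np.ones(len(t), dtype=np.float32)
    else:
        wv = np.asarray(class_weights, dtype=np.float32)[t]
    wsum = wv.sum()
    loss = -(wv * logp[np.arange(len(t)), t]).sum() / wsum
    probs = np.exp(logp)

    def backward(g):
        gflat = probs.copy()
        gflat[np.arange(len(t)), t] -= 1.0
        gflat *= (g * wv / wsum)[:, None]
        if ld.ndim == 4:
            glog = gflat.reshape(ld.shape[0], ld.shape[2], ld.shape[3], N).transpose(0, 3, 1, 2)
        else:
            glog = gflat
        logits._accumulate(glog.astype(np.float32))

    return _make(np.float32(loss), (logits,), backward)
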