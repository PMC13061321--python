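"""Compact reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the segmentation network needs:
broadcast-aware arithmetic, batched matmul, shape ops, indexed take,
elementwise nonlinearities, reductions, 3D convolution (stride/dilation,
zero 'same' padding) and an axis-wise linear map used for trilinear
upsampling.  Gradients are accumulated by topological-order backpropagation
from a scalar (or any tensor via an explicit output gradient).

All data is float32; computations that need extra headroom (softmax
normalizers, variance) subtract detached shifts instead of promoting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "dot_axis", "take", "concat", "softmax", "log_softmax",
           "normalize", "cross_entropy_onehot", "relu", "gelu", "tanh", "exp", "log",
           "sqrt", "upsample3d", "no_grad"]


class _NoGrad:
    enabled = False

    def __enter__(self):
        self.prev = _NoGrad.enabled
        _NoGrad.enabled = True

    def __exit__(self, *exc):
        _NoGrad.enabled = self.prev


def no_grad():
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad.enabled
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad.enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.requires_grad:
            g = np.asarray(g, dtype=np.float32)
            self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- basics -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g, a=self, p=p):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, a=self, old=old):
            a._accum(g.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g, a=self, inv=inv):
            a._accum(np.transpose(g, inv))

        return Tensor._result(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- elementwise nonlinearities -------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, a=x, mask=mask):
        a._accum(g * mask)

    return Tensor._result(x.data * mask, (x,), backward)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g, a=x, o=out_data):
        a._accum(g * o)

    return Tensor._result(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g, a=x):
        a._accum(g / a.data)

    return Tensor._result(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def backward(g, a=x, o=out_data):
        a._accum(g * 0.5 / o)

    return Tensor._result(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g, a=x, o=out_data):
        a._accum(g * (1.0 - o * o))

    return Tensor._result(out_data, (x,), backward)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """tanh approximation of the Gaussian error linear unit (fused)."""
    xd = x.data
    u = _GELU_C * (xd + 0.044715 * (xd * xd * xd))
    t = np.tanh(u)
    out_data = 0.5 * xd * (1.0 + t)

    def backward(g, a=x, xd=xd, t=t):
        du = _GELU_C * (1.0 + 3 * 0.044715 * xd * xd)
        a._accum(g * (0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t * t) * du))

    return Tensor._result(out_data, (x,), backward)


# -- reductions / normalizations ------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g, a=x, y=y, axis=axis):
        a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor._result(y, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    z = x.data - shift
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def backward(g, a=x, axis=axis, p=np.exp(out_data)):
        a._accum(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor._result(out_data, (x,), backward)


def normalize(x: Tensor, gamma: Tensor, beta: Tensor, axes, eps: float) -> Tensor:
    """Fused (x - mean)/std * gamma + beta with mean/std over ``axes``.

    ``gamma``/``beta`` must broadcast against x (e.g. (C,) for layer norm
    over the last axis, (1,C,1,1,1) views for batch norm)."""
    axes = tuple(axes)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = xc / std
    out_data = xhat * gamma.data + beta.data

    def backward(g, a=x, gm=gamma, bt=beta, xhat=xhat, std=std, axes=axes):
        gxhat = g * gm.data
        if a.requires_grad:
            m1 = gxhat.mean(axis=axes, keepdims=True)
            m2 = (gxhat * xhat).mean(axis=axes, keepdims=True)
            a._accum((gxhat - m1 - xhat * m2) / std)
        gm._accum(_unbroadcast(g * xhat, gm.data.shape))
        bt._accum(_unbroadcast(g, bt.data.shape))

    return Tensor._result(out_data, (x, gamma, beta), backward)


def cross_entropy_onehot(logits: Tensor, onehot: np.ndarray, axis: int = 1) -> Tensor:
    """Mean cross-entropy between softmax(logits) and a one-hot target
    (fused: backward is (softmax - onehot)/n)."""
    onehot = np.asarray(onehot, dtype=np.float32)
    shift = logits.data.max(axis=axis, keepdims=True)
    z = logits.data - shift
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    logp = z - lse
    n = logits.data.size // logits.data.shape[axis]
    out = -(onehot * logp).sum() / n

    def backward(g, a=logits, p=np.exp(logp), onehot=onehot, n=n):
        a._accum(g * (p - onehot) / n)

    return Tensor._result(np.float32(out), (logits,), backward)


# -- structural ops --------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, ts=tuple(tensors), axis=axis, splits=splits):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._result(out_data, tuple(tensors), backward)


def take(x: Tensor, indices, axis: int = 0) -> Tensor:
    indices = np.asarray(indices)
    out_data = np.take(x.data, indices, axis=axis)

    def backward(g, a=x, indices=indices, axis=axis):
        full = np.zeros_like(a.data)
        gm = np.moveaxis(g, axis, 0)
        fm = np.moveaxis(full, axis, 0)
        np.add.at(fm, indices, gm)
        a._accum(full)

    return Tensor._result(out_data, (x,), backward)


def dot_axis(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """Apply the constant linear map ``m`` (out x in) along one axis."""
    m = np.asarray(m, dtype=np.float32)
    xd = np.moveaxis(x.data, axis, 0)
    out = np.moveaxis(np.tensordot(m, xd, axes=([1], [0])), 0, axis)

    def backward(g, a=x, m=m, axis=axis):
        gm = np.moveaxis(g, axis, 0)
        ga = np.moveaxis(np.tensordot(m.T, gm, axes=([1], [0])), 0, axis)
        a._accum(ga)

    return Tensor._result(out, (x,), backward)


# -- 3D convolution ---------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, stride: int = 1, dilation: int = 1) -> Tensor:
    """3D convolution with zero 'same'-style padding.

    ``x`` is (B, Cin, H, W, D), ``w`` is (Cout, Cin, k, k, k) with odd k.
    Padding is ``dilation * (k - 1) // 2`` per side, so stride 1 preserves
    the spatial shape and stride 2 halves even extents.
    """
    k = w.data.shape[2]
    if k % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {k}")
    d, s = int(dilation), int(stride)
    B, cin, H, W, D = x.data.shape
    if w.data.shape[1] != cin:
        raise ValueError(f"weight expects {w.data.shape[1]} input channels, got {cin}")
    cout = w.data.shape[0]

    if k == 1 and s == 1:
        # pointwise: a single channel-mixing matmul
        wmat = w.data.reshape(cout, cin)
        xm = x.data.reshape(B, cin, -1)
        out_data = np.einsum("oc,bcs->bos", wmat, xm, optimize=True).reshape(
            B, cout, H, W, D)

        def backward(g, a=x, wt=w, xm=xm, wmat=wmat):
            gm = g.reshape(B, cout, -1)
            if wt.requires_grad:
                gw = np.einsum("bos,bcs->oc", gm, xm, optimize=True)
                wt._accum(gw.reshape(wt.data.shape))
            if a.requires_grad:
                a._accum(np.einsum("oc,bos->bcs", wmat, gm,
                                   optimize=True).reshape(a.data.shape))

        return Tensor._result(out_data, (x, w), backward)

    pad = d * (k - 1) // 2
    if pad:
        xp = np.zeros((B, cin, H + 2 * pad, W + 2 * pad, D + 2 * pad), dtype=np.float32)
        xp[:, :, pad : pad + H, pad : pad + W, pad : pad + D] = x.data
    else:
        xp = x.data
    span = d * (k - 1) + 1
    Ho = (H + 2 * pad - span) // s + 1
    Wo = (W + 2 * pad - span) // s + 1
    Do = (D + 2 * pad - span) // s + 1
    if min(Ho, Wo, Do) < 1:
        raise ValueError(f"input {x.data.shape} too small for kernel span {span}")
    offsets = [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]
    kk = len(offsets)

    def _slice(arr, i, j, l):
        return arr[:, :,
                   i * d : i * d + s * (Ho - 1) + 1 : s,
                   j * d : j * d + s * (Wo - 1) + 1 : s,
                   l * d : l * d + s * (Do - 1) + 1 : s]

    # two strategies: full im2col (one GEMM; wins when the column matrix is
    # small) vs shifted-slice accumulation (one small GEMM per offset; wins
    # at large spatial sizes where the 6-axis im2col transpose thrashes)
    n_out = B * Ho * Wo * Do
    if n_out * kk * cin <= (1 << 21):
        cols = np.empty((kk, B, cin, Ho, Wo, Do), dtype=np.float32)
        for idx, (i, j, l) in enumerate(offsets):
            cols[idx] = _slice(xp, i, j, l)
        cols2 = np.ascontiguousarray(cols.transpose(1, 3, 4, 5, 0, 2)).reshape(
            n_out, kk * cin)
        wmat = np.ascontiguousarray(w.data.transpose(0, 2, 3, 4, 1)).reshape(
            cout, kk * cin)
        out_data = (cols2 @ wmat.T).reshape(B, Ho, Wo, Do, cout).transpose(
            0, 4, 1, 2, 3)

        def backward(g, a=x, wt=w):
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, cout)
            if wt.requires_grad:
                gw = (gm.T @ cols2).reshape(cout, kk, cin).transpose(0, 2, 1)
                wt._accum(np.ascontiguousarray(gw).reshape(cout, cin, k, k, k))
            if a.requires_grad:
                gcols = (gm @ wmat).reshape(B, Ho, Wo, Do, kk, cin).transpose(
                    4, 0, 5, 1, 2, 3)
                gxp = np.zeros_like(xp)
                for idx, (i, j, l) in enumerate(offsets):
                    target = _slice(gxp, i, j, l)
                    target += gcols[idx]
                if pad:
                    a._accum(gxp[:, :, pad : pad + H, pad : pad + W, pad : pad + D])
                else:
                    a._accum(gxp)

        return Tensor._result(out_data, (x, w), backward)

    acc = np.zeros((cout, B, Ho, Wo, Do), dtype=np.float32)
    for (i, j, l) in offsets:
        acc += np.tensordot(w.data[:, :, i, j, l], _slice(xp, i, j, l),
                            axes=([1], [1]))
    out_data = np.moveaxis(acc, 0, 1)

    def backward(g, a=x, wt=w):
        gm = np.moveaxis(g, 1, 0)  # (Cout, B, Ho, Wo, Do)
        if wt.requires_grad:
            gw = np.empty_like(wt.data)
            for (i, j, l) in offsets:
                gw[:, :, i, j, l] = np.tensordot(
                    gm, _slice(xp, i, j, l), axes=([1, 2, 3, 4], [0, 2, 3, 4]))
            wt._accum(gw)
        if a.requires_grad:
            gxp = np.zeros_like(xp)
            for (i, j, l) in offsets:
                gi = np.tensordot(wt.data[:, :, i, j, l], gm, axes=([0], [0]))
                target = _slice(gxp, i, j, l)
                target += np.moveaxis(gi, 0, 1)
            if pad:
                a._accum(gxp[:, :, pad : pad + H, pad : pad + W, pad : pad + D])
            else:
                a._accum(gxp)

    return Tensor._result(out_data, (x, w), backward)


def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """1D linear interpolation matrix for integer-factor upsampling
    (half-voxel aligned, edge-clamped)."""
    n_out = n_in * factor
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        c = (o + 0.5) / factor - 0.5
        i0 = int(np.floor(c))
        t = c - i0
        lo = min(max(i0, 0), n_in - 1)
        hi = min(max(i0 + 1, 0), n_in - 1)
        m[o, lo] += 1.0 - t
        m[o, hi] += t
    return m


def upsample3d(x: Tensor, factor: int) -> Tensor:
    """Trilinear upsampling of (B, C, H, W, D) by an integer factor."""
    out = x
    for axis in (2, 3, 4):
        out = dot_axis(out, _interp_matrix(out.data.shape[axis], factor), axis)
    return out
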