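"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float32
``ndarray`` and remembers how it was produced; :func:`Tensor.backward`
replays the tape in reverse topological order.  Only the operations the
two-stream lesion classifier needs are implemented, each as a fused
forward/backward pair so the graph stays shallow and memory-light.

Convolutions are evaluated by shift decomposition: a k x k convolution is
k**2 channel-mixing GEMMs over strided views of the padded input.  This
avoids materialising im2col buffers (which for 224 x 224 x 64 maps would
run to gigabytes) while keeping all heavy arithmetic inside BLAS.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A float32 array with an optional gradient and provenance record."""

    __slots__ = ("data", "grad", "requires_grad", "retains_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self.retains_grad = False
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def retain_grad(self):
        self.retains_grad = True

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            parent_grads = node._backward(node.grad)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if not (parent.requires_grad or parent._parents or parent.retains_grad):
                    continue
                if parent.grad is None:
                    parent.grad = pg.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + pg
            if not (node is self or node.requires_grad or node.retains_grad):
                node.grad = None  # free intermediate gradients eagerly
            # release the closure (and the forward arrays it captured) as we go,
            # so activation memory is reclaimed during the backward sweep
            node._backward = None
            node._parents = ()


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents or p.retains_grad for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum (shapes must match; used for residual merges)."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    return _node(a.data + b.data, (a, b), lambda g: (g, g))


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    # the mask is recovered from the output itself; nothing extra is stored
    return _node(out, (x,), lambda g: (g * (out > 0),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(data, tuple(tensors), backward)


def flatten(x: Tensor) -> Tensor:
    shape = x.data.shape
    return _node(x.data.reshape(shape[0], -1), (x,), lambda g: (g.reshape(shape),))


# ---------------------------------------------------------------------------
# dense / loss
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with ``w`` of shape (out_features, in_features)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def backward(g):
        gx = g @ w.data
        gw = g.T @ x.data
        gb = g.sum(axis=0) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over the batch, from raw logits."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    probs = softmax(logits.data)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(g):
        gl = probs.copy()
        gl[np.arange(n), labels] -= 1.0
        return (g * gl / n,)

    return _node(np.float32(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# convolution (NCHW)
# ---------------------------------------------------------------------------

def _nhwc_padded(x_nchw, padding: int):
    """Channels-last padded copy; tap windows become contiguous memory runs."""
    xt = np.ascontiguousarray(x_nchw.transpose(0, 2, 3, 1))
    if padding:
        xt = np.pad(xt, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    return xt


def _conv_core_nhwc(xt: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Correlate a padded NHWC input with (Cout,Cin,kh,kw) weights.

    One GEMM per kernel row: a window over (kw, Cin) is a contiguous run in
    NHWC memory, so an overlapping strided view yields a (N*Ho*Wo, kw*Cin)
    matrix whose large inner dimension keeps BLAS efficient.  Returns NHWC.
    """
    n, hp, wp, cin = xt.shape
    cout, _, kh, kw = w.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s_n, s_h, s_w, s_c = xt.strides
    # wmat[i] rows are ordered (w_offset, channel) to match the memory run
    wmat = np.ascontiguousarray(w.transpose(2, 3, 1, 0)).reshape(kh, kw * cin, cout)
    out2d = np.zeros((n * ho * wo, cout), dtype=np.float32)
    for i in range(kh):
        ai = np.lib.stride_tricks.as_strided(
            xt[:, i:], shape=(n, ho, wo, kw * cin),
            strides=(s_n, s_h * stride, s_w * stride, s_c))
        out2d += ai.reshape(-1, kw * cin) @ wmat[i]
    return out2d.reshape(n, ho, wo, cout)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weights (Cout, Cin, kh, kw)."""
    n, cin, h, wid = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    if h + 2 * padding < kh or wid + 2 * padding < kw:
        raise ValueError("conv2d: kernel exceeds padded input extent")

    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        return _conv1x1(x, w, b)

    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wid + 2 * padding - kw) // stride + 1
    out = _conv_core_nhwc(_nhwc_padded(x.data, padding), w.data, stride)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        xt = _nhwc_padded(x.data, padding)  # re-derived, not kept on the tape
        s_n, s_h, s_w, s_c = xt.strides
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        gw = np.empty_like(w.data)
        for i in range(kh):
            ai = np.lib.stride_tricks.as_strided(
                xt[:, i:], shape=(n, ho, wo, kw * cin),
                strides=(s_n, s_h * stride, s_w * stride, s_c))
            gwi = g2d.T @ ai.reshape(-1, kw * cin)  # (Cout, kw*Cin)
            gw[:, :, i, :] = gwi.reshape(cout, kw, cin).transpose(0, 2, 1)
        need_gx = bool(x.requires_grad or x._parents or x.retains_grad)
        gx = None
        if need_gx:
            if stride == 1:
                # input gradient = correlation of g with the flipped,
                # channel-transposed kernel at complementary padding
                wflip = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                gt = _nhwc_padded(g, kh - 1 - padding)
                gx = _conv_core_nhwc(gt, wflip, 1)
                gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
            else:
                gxt = np.zeros_like(xt)
                hi_stop = (ho - 1) * stride + 1
                wi_stop = (wo - 1) * stride + 1
                gnhwc = g2d.reshape(n, ho, wo, cout)
                for i in range(kh):
                    for j in range(kw):
                        gxs = gnhwc @ w.data[:, :, i, j]
                        gxt[:, i:i + hi_stop:stride, j:j + wi_stop:stride, :] += gxs
                if padding:
                    gxt = gxt[:, padding:padding + h, padding:padding + wid, :]
                gx = np.ascontiguousarray(gxt.transpose(0, 3, 1, 2))
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, backward)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution kept in NCHW: a batched channel-mixing GEMM."""
    n, cin, h, wid = x.data.shape
    cout = w.data.shape[0]
    w2 = w.data.reshape(cout, cin)
    out = np.matmul(w2[None], x.data.reshape(n, cin, h * wid)).reshape(n, cout, h, wid)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        g3 = g.reshape(n, cout, h * wid)
        gw = np.tensordot(g3, x.data.reshape(n, cin, h * wid), axes=([0, 2], [0, 2]))
        need_gx = bool(x.requires_grad or x._parents or x.retains_grad)
        gx = None
        if need_gx:
            gx = np.matmul(w2.T[None], g3).reshape(n, cin, h, wid)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw.reshape(w.data.shape), gb) if b is not None \
            else (gx, gw.reshape(w.data.shape))

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out.astype(np.float32, copy=False), parents, backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    n, c, h, w = x.data.shape
    if kernel == 2 and stride == 2 and padding == 0 and h % 2 == 0 and w % 2 == 0:
        return _max_pool2x2(x)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1).astype(np.uint8)
    out = np.take_along_axis(win, arg[..., None].astype(np.intp), axis=-1)[..., 0]
    del win

    def backward(g):
        gi, gj = np.divmod(arg, kernel)
        # flat scatter-add into the padded input (windows may overlap)
        nn_, cc, hh, ww = np.ogrid[:n, :c, :ho, :wo]
        r = hh * stride + gi
        s = ww * stride + gj
        flat_idx = (((nn_ * c + cc) * hp + r) * wp + s).ravel()
        gxp = np.bincount(flat_idx, weights=g.ravel(), minlength=n * c * hp * wp)
        gxp = gxp.reshape(n, c, hp, wp).astype(np.float32)
        return (gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp,)

    return _node(np.ascontiguousarray(out), (x,), backward)


def _max_pool2x2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2 max pool without materialising windows.

    The backward pass routes the gradient to every window position equal
    to the maximum; exact ties therefore each receive the gradient, which
    only occurs at zero plateaus created by a preceding ReLU where the
    upstream ReLU gradient mask annihilates them anyway.
    """
    a = x.data[:, :, 0::2, 0::2]
    b = x.data[:, :, 0::2, 1::2]
    c = x.data[:, :, 1::2, 0::2]
    d = x.data[:, :, 1::2, 1::2]
    out = np.maximum(np.maximum(a, b), np.maximum(c, d))

    def backward(g):
        gx = np.empty_like(x.data)
        gx[:, :, 0::2, 0::2] = np.where(a == out, g, 0.0)
        gx[:, :, 0::2, 1::2] = np.where(b == out, g, 0.0)
        gx[:, :, 1::2, 0::2] = np.where(c == out, g, 0.0)
        gx[:, :, 1::2, 1::2] = np.where(d == out, g, 0.0)
        return (gx,)

    return _node(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    stride = stride or kernel
    if stride != kernel:
        raise NotImplementedError("avg_pool2d supports non-overlapping windows only")
    n, c, h, w = x.data.shape
    ho, wo = h // kernel, w // kernel
    v = x.data[:, :, :ho * kernel, :wo * kernel]
    out = v.reshape(n, c, ho, kernel, wo, kernel).mean(axis=(3, 5))

    def backward(g):
        gx = np.zeros_like(x.data)
        expand = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3) / (kernel * kernel)
        gx[:, :, :ho * kernel, :wo * kernel] = expand
        return (gx,)

    return _node(out, (x,), backward)


def gem_pool2d(x: Tensor, p: float, eps: float = 1e-6) -> Tensor:
    """Generalized-mean pooling over the spatial extent: (N,C,H,W) -> (N,C).

    Requires non-negative activations (post-ReLU contract); ``eps`` keeps
    the gradient finite at exact zeros.
    """
    if p < 1:
        raise ValueError(f"GeM exponent must satisfy p >= 1, got {p}")
    if np.any(x.data < 0):
        raise ValueError("GeM pooling requires non-negative activations")
    n, c, h, w = x.data.shape
    shifted = x.data + eps
    powered = shifted ** p
    m = powered.mean(axis=(2, 3))
    out = m ** (1.0 / p)

    def backward(g):
        # d out / d x = out^(1-p) * (x+eps)^(p-1) / (H*W)
        coeff = (g * out ** (1.0 - p) / (h * w))[:, :, None, None]
        return (coeff * shifted ** (p - 1.0),)

    return _node(out.astype(np.float32), (x,), backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.9, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W); updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = np.einsum("nchw,nchw->c", x.data, x.data,
                        optimize=True) / (x.data.shape[0] * x.data.shape[2] *
                                          x.data.shape[3]) - mean * mean
        var = np.maximum(var, 0.0)
        running_mean *= momentum
        running_mean += (1 - momentum) * mean
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    mean = mean.astype(np.float32)
    scale = gamma.data * inv_std
    out = x.data * scale[None, :, None, None] + \
        (beta.data - mean * scale)[None, :, None, None]

    def backward(g):
        # xhat is recomputed from x rather than stored on the tape
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        if training:
            gxhat = g * gamma.data[None, :, None, None]
            t1 = gxhat - gxhat.mean(axis=(0, 2, 3))[None, :, None, None]
            xhat *= (gxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
            t1 -= xhat
            gx = inv_std[None, :, None, None] * t1
        else:
            gx = g * (gamma.data * inv_std)[None, :, None, None]
        return gx.astype(np.float32, copy=False), ggamma, gbeta

    return _node(out.astype(np.float32, copy=False), (x, gamma, beta), backward)
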