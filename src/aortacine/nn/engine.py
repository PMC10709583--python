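"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the segmentation network needs:
elementwise arithmetic, sigmoid/tanh/ReLU, stride-1 2-D convolution with
"same" padding, 2x2 max-pooling, 2x nearest-neighbour up-sampling, channel
concatenation, batch normalisation, dropout and reductions.  Arrays follow
the (N, C, H, W) layout; a cine batch of B sequences with T frames is laid
out sequence-major along N (row ``b*T + t``), so one convolution call covers
every frame of every sequence at once (time-distributed execution).

Dtypes follow the inputs: float64 parameters give float64 graphs (used by
the closed-form unit checks), float32 parameters keep training fast.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of this (scalar) node into the graph leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs unrolled over time get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            if node._parents:
                node._backward = None  # free closures as we go
                node.grad = None if node is not self else self.grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self):
        return tsum(self)

    def mean(self):
        return mul(tsum(self), 1.0 / self.data.size)


class Parameter(Tensor):
    """A leaf tensor holding trainable weights."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ops -------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * out_data / b.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def power(a, exponent: float):
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def backward(g):
        _accum(a, g * exponent * a.data ** (exponent - 1.0))

    return Tensor(out_data, (a,), backward)


def tsum(a: Tensor):
    a = _as_tensor(a)
    out_data = np.asarray(a.data.sum())

    def backward(g):
        _accum(a, np.broadcast_to(g, a.data.shape))

    return Tensor(out_data, (a,), backward)


def relu(a: Tensor):
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return Tensor(out_data, (a,), backward)


def sigmoid(a: Tensor):
    a = _as_tensor(a)
    out_data = expit(a.data)

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, (a,), backward)


def tanh(a: Tensor):
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return Tensor(out_data, (a,), backward)


# -- structural ops --------------------------------------------------------

def reshape(a: Tensor, shape):
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return Tensor(out_data, (a,), backward)


def concat_channels(tensors):
    """Concatenate along the channel axis (axis 1)."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            _accum(t, g[:, start:start + s])
            start += s

    return Tensor(out_data, tuple(tensors), backward)


def stride_rows(a: Tensor, start: int, step: int):
    """Select rows ``start::step`` along axis 0 (frame t of a b-major batch)."""
    a = _as_tensor(a)
    out_data = a.data[start::step]

    def backward(g):
        full = np.zeros_like(a.data)
        full[start::step] = g
        _accum(a, full)

    return Tensor(out_data, (a,), backward)


def interleave_rows(tensors):
    """Inverse of frame extraction: T tensors of (B, ...) -> (B*T, ...) b-major."""
    tensors = [_as_tensor(t) for t in tensors]
    T = len(tensors)
    stacked = np.stack([t.data for t in tensors], axis=1)  # (B, T, ...)
    out_shape = (stacked.shape[0] * T,) + stacked.shape[2:]
    out_data = stacked.reshape(out_shape)

    def backward(g):
        gr = g.reshape(stacked.shape)
        for t_idx, t in enumerate(tensors):
            _accum(t, gr[:, t_idx])

    return Tensor(out_data, tuple(tensors), backward)


# -- convolution -----------------------------------------------------------

def _same_pads(k: int) -> tuple[int, int]:
    # Odd kernels pad symmetrically; even kernels pad one extra on the
    # bottom/right (the common "same" convention for 2x2 up-convolutions).
    return (k - 1) // 2, k // 2


def _im2col(x, kh, kw, pads):
    (pt, pb), (pl, pr) = pads
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _conv_forward(x, w, pads):
    f, c, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, pads)
    out = cols @ w.reshape(f, c * kh * kw).T
    return out.reshape(x.shape[0], ho, wo, f).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None):
    """Stride-1 "same" 2-D convolution; ``w`` is (F, C, kh, kw), ``b`` is (F,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    f, c, kh, kw = w.data.shape
    pads = (_same_pads(kh), _same_pads(kw))
    out_data, cols = _conv_forward(x.data, w.data, pads)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(-1, f)
        if w.requires_grad:
            _accum(w, (gm.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, gm.sum(axis=0))
        if x.requires_grad:
            # gradient w.r.t. the input is the "full" correlation with the
            # spatially flipped, channel-transposed kernel
            w_flip = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            bp = tuple((k - 1 - p0, k - 1 - p1) for k, (p0, p1) in
                       zip((kh, kw), pads))
            gx, _ = _conv_forward(g, w_flip, bp)
            _accum(x, gx)

    return Tensor(out_data, parents, backward)


# -- pooling / resampling --------------------------------------------------

def maxpool2(x: Tensor):
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, gx.reshape(n, c, h, w))

    return Tensor(out_data, (x,), backward)


def upsample2(x: Tensor):
    """2x nearest-neighbour up-sampling."""
    x = _as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        _accum(x, gx)

    return Tensor(out_data, (x,), backward)


# -- normalisation / regularisation ---------------------------------------

def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
              training: bool, momentum: float = 0.9, eps: float = 1e-5):
    """Per-channel batch normalisation over (N, H, W).

    ``running`` carries the inference statistics {"mean", "var"} and is
    updated in place during training with an exponential moving average.
    """
    x = _as_tensor(x)
    c = x.data.shape[1]
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = momentum
        running["mean"] = m * running["mean"] + (1 - m) * mean
        running["var"] = m * running["var"] + (1 - m) * var
    else:
        mean, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) / std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data.reshape(1, c, 1, 1) / std.reshape(1, c, 1, 1)
            if training:
                nred = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gmean = g.mean(axis=axes).reshape(1, c, 1, 1)
                gxhat = (g * xhat).sum(axis=axes).reshape(1, c, 1, 1) / nred
                _accum(x, gs * (g - gmean - xhat * gxhat))
            else:
                _accum(x, gs * g)

    return Tensor(out_data, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool):
    x = _as_tensor(x)
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out_data = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return Tensor(out_data, (x,), backward)


# -- optimiser -------------------------------------------------------------

class Adam:
    """Adam with a constant learning rate (the training protocol's optimiser)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    """He-normal initialisation: N(0, sqrt(2/fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)
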