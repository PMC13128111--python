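"""Minimal CPU tensor library with reverse-mode autodiff.

The segmentation network in this package needs a small, well-defined set of
differentiable primitives: dense and strided convolutions, transposed
convolutions, batch/layer normalisation, batched matrix products for windowed
attention, a handful of element-wise nonlinearities, pooling, and linear
spatial resizing.  This module implements exactly that set on top of numpy,
plus an AdamW optimiser and a deterministic multiply-accumulate (MAC) tally
used by the accounting layer.

Conventions
-----------
* All arrays are float32; feature maps are laid out (B, C, H, W).
* ``Tensor`` records a tape of backward closures; ``Tensor.backward`` runs a
  topological sweep.  Inference code should run inside ``no_grad()``.
* Convolutions that are immediately followed by a batch-normalisation layer
  are bias-free: a bias ahead of BN is exactly gradient-dead (BN subtracts
  the per-channel mean), so such a parameter could never be trained.
* MAC counting covers convolutions, transposed convolutions, linear layers
  and explicitly-counted attention matmuls; element-wise work, softmax and
  spatial resizing are not charged (one MAC is reported as one FLOP).
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy import special as _sp_special

# ---------------------------------------------------------------------------
# global state: RNG, grad mode, MAC tally
# ---------------------------------------------------------------------------

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the module RNG used for parameter init, dropout and shuffling."""
    global _RNG
    _RNG = np.random.default_rng(int(seed))


def get_rng() -> np.random.Generator:
    return _RNG


_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class MacTally:
    """Accumulates multiply-accumulate counts while active."""

    def __init__(self) -> None:
        self.n = 0


_MAC_STACK: list[MacTally] = []


@contextmanager
def track_macs(tally: MacTally):
    _MAC_STACK.append(tally)
    try:
        yield tally
    finally:
        _MAC_STACK.remove(tally)


def add_macs(n: int) -> None:
    for t in _MAC_STACK:
        t.n += int(n)


# ---------------------------------------------------------------------------
# Tensor and autodiff core
# ---------------------------------------------------------------------------


def _f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


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
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, powc(other, -1.0))

    def __rtruediv__(self, other):
        return mul(powc(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def powc(a, p: float) -> Tensor:
    a = _wrap(a)
    data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b, count: bool = False) -> Tensor:
    """Batched matrix product.  ``count=True`` charges MACs (attention)."""
    a, b = _wrap(a), _wrap(b)
    data = np.matmul(a.data, b.data)
    if count and _MAC_STACK:
        # product of all output elements times the contracted dim
        add_macs(data.size // data.shape[-1] * a.data.shape[-1] * data.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            gg = np.expand_dims(g, axes)
        a._accum(np.broadcast_to(gg, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax % a.data.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def tmax(a: Tensor, axis: int, keepdims=False) -> Tensor:
    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data)
    # distribute ties evenly so the op stays a valid subgradient
    mask = mask / mask.sum(axis=axis, keepdims=True)
    out_data = data if keepdims else np.squeeze(data, axis=axis)

    def backward(g):
        if a.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(mask.astype(np.float32) * gg)

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accum(g[tuple(sl)])
            start += s

    return _make(data, tuple(tensors), backward)


def roll2d(a: Tensor, shifts: tuple[int, int], axes=(2, 3)) -> Tensor:
    data = np.roll(a.data, shifts, axis=axes)

    def backward(g):
        if a.requires_grad:
            a._accum(np.roll(g, (-shifts[0], -shifts[1]), axis=axes))

    return _make(data, (a,), backward)


# -- nonlinearities ---------------------------------------------------------


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (a.data > 0))

    return _make(data, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    x = a.data
    cdf = 0.5 * (1.0 + _sp_special.erf(x / math.sqrt(2.0))).astype(np.float32)
    data = x * cdf

    def backward(g):
        if a.requires_grad:
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            a._accum(g * (cdf + x * pdf).astype(np.float32))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = _sp_special.expit(a.data).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            a._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return _make(s, (a,), backward)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse
    s = np.exp(data)

    def backward(g):
        if a.requires_grad:
            a._accum(g - s * g.sum(axis=axis, keepdims=True))

    return _make(data, (a,), backward)


# -- convolution family -----------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, ho: int, wo: int):
    b, c = xp.shape[:2]
    cols = np.empty((b, c, kh, kw, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
    return cols.reshape(b, c * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, xshape, kh, kw, sh, sw, ph, pw, ho, wo):
    b, c, h, w = xshape
    xp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=np.float32)
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += cols[:, :, i, j]
    if ph or pw:
        return xp[:, :, ph:ph + h, pw:pw + w]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation, weight (O, C, kh, kw)."""
    bs, c, h, wdt = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride, stride, ho, wo)
    w2 = w.data.reshape(o, -1)
    out = np.matmul(w2[None], cols).reshape(bs, o, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)
    if _MAC_STACK:
        add_macs(bs * o * ho * wo * c * kh * kw)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gr = g.reshape(bs, o, ho * wo)
        if w.requires_grad:
            gw = np.einsum('bol,bcl->oc', gr, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T[None], gr)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, stride,
                             padding, padding, ho, wo))

    return _make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Transposed conv with kernel == stride (non-overlapping upsampling).

    Weight layout (C_in, C_out, k, k).
    """
    bs, c, h, wdt = x.data.shape
    c2, o, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv_transpose2d channel mismatch: {c} vs {c2}")
    if kh != stride or kw != stride:
        raise ValueError("conv_transpose2d implemented for kernel == stride")
    out = np.empty((bs, o, h * stride, wdt * stride), dtype=np.float32)
    xf = x.data.reshape(bs, c, h * wdt)
    for i in range(kh):
        for j in range(kw):
            y = np.matmul(w.data[:, :, i, j].T[None], xf).reshape(bs, o, h, wdt)
            out[:, :, i::stride, j::stride] = y
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)
    if _MAC_STACK:
        add_macs(bs * o * h * stride * wdt * stride * c)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad or x.requires_grad:
            dx = np.zeros_like(x.data) if x.requires_grad else None
            for i in range(kh):
                for j in range(kw):
                    gsub = g[:, :, i::stride, j::stride]
                    gf = gsub.reshape(bs, o, h * wdt)
                    if w.requires_grad:
                        gw = np.einsum('bcl,bol->co', xf, gf, optimize=True)
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, i, j] += gw
                    if dx is not None:
                        dx += np.matmul(w.data[:, :, i, j][None], gf).reshape(
                            bs, c, h, wdt)
            if dx is not None:
                x._accum(dx)

    return _make(out, parents, backward)


# -- pooling / resizing -----------------------------------------------------


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    bs, c, h, w = x.data.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    stack = np.empty((kernel * kernel, bs, c, ho, wo), dtype=np.float32)
    for i in range(kernel):
        for j in range(kernel):
            stack[i * kernel + j] = xp[:, :, i:i + stride * ho:stride,
                                       j:j + stride * wo:stride]
    arg = stack.argmax(axis=0)
    out = np.take_along_axis(stack, arg[None], axis=0)[0]

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.zeros_like(xp)
        for idx in range(kernel * kernel):
            i, j = divmod(idx, kernel)
            m = (arg == idx)
            gp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += g * m
        x._accum(gp[:, :, padding:padding + h, padding:padding + w])

    return _make(out, (x,), backward)


def _avg_pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Adaptive average pooling as a (n_out, n_in) row-stochastic matrix.

    Output cell r averages input indices floor(r*n_in/n_out) ..
    ceil((r+1)*n_in/n_out)-1 (the common adaptive-pooling convention).
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for r in range(n_out):
        a = (r * n_in) // n_out
        bnd = -(-((r + 1) * n_in) // n_out)  # ceil
        m[r, a:bnd] = 1.0 / (bnd - a)
    return m


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix, half-pixel (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - frac
        m[o, i1c] += frac
    return m


def _separable_resize(x: Tensor, rmat: np.ndarray, cmat: np.ndarray) -> Tensor:
    """Apply row/column resize matrices over the trailing two axes."""
    data = np.einsum('oi,bcij,pj->bcop', rmat, x.data, cmat, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum('oi,bcop,pj->bcij', rmat, g, cmat, optimize=True))

    return _make(data, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    h, w = x.data.shape[2], x.data.shape[3]
    return _separable_resize(x, _avg_pool_matrix(h, out_hw[0]),
                             _avg_pool_matrix(w, out_hw[1]))


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    h, w = x.data.shape[2], x.data.shape[3]
    return _separable_resize(x, _bilinear_matrix(h, out_hw[0]),
                             _bilinear_matrix(w, out_hw[1]))


def dropout(x: Tensor, p: float, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (_RNG.random(x.data.shape) < keep).astype(np.float32) / keep
    return mul(x, Tensor(mask))


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for n, m in self._modules.items():
            yield from m.named_modules(prefix + n + ".")

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield (prefix + n, b)
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            state["buffer::" + n] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for n, p in params.items():
            p.data[...] = state[n]
        bufs = {n: (m, bn) for pn, m in self.named_modules()
                for bn in m._buffers
                for n in [(pn + "." + bn).lstrip(".")]}
        for key, val in state.items():
            if key.startswith("buffer::"):
                name = key[len("buffer::"):]
                m, bn = bufs[name]
                m._buffers[bn][...] = val
                object.__setattr__(m, bn, m._buffers[bn])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def trunc_normal_(shape, std: float = 0.02) -> np.ndarray:
    a = _RNG.normal(0.0, std, size=shape)
    np.clip(a, -2 * std, 2 * std, out=a)
    return a.astype(np.float32)


def _kaiming(shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return (_RNG.normal(0.0, std, size=shape)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming((c_out, c_in, kernel, kernel),
                                         c_in * kernel * kernel))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, kernel, stride, bias=True):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(_kaiming((c_in, c_out, kernel, kernel), c_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, d_in, d_out, bias=True, init_std: float | None = 0.02):
        super().__init__()
        if init_std is None:
            w = _kaiming((d_out, d_in), d_in)
        else:
            w = trunc_normal_((d_out, d_in), init_std)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        if _MAC_STACK:
            add_macs(x.data.size // x.data.shape[-1]
                     * self.weight.data.shape[1] * self.weight.data.shape[0])
        y = matmul(x, transpose(self.weight, (1, 0)))
        if self.bias is not None:
            y = add(y, self.bias)
        return y


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.size / x.data.shape[1]
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mu
            self.running_var *= (1 - self.momentum)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        out = xhat * self.weight.data.reshape(1, -1, 1, 1) \
            + self.bias.data.reshape(1, -1, 1, 1)
        training = self.training
        w, b = self.weight, self.bias

        def backward(g):
            if w.requires_grad:
                w._accum((g * xhat).sum(axis=(0, 2, 3)))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * w.data.reshape(1, -1, 1, 1)
                if training:
                    n = x.data.size / x.data.shape[1]
                    t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (dxhat - t1 / n - xhat * t2 / n) * inv.reshape(1, -1, 1, 1)
                else:
                    dx = dxhat * inv.reshape(1, -1, 1, 1)
                x._accum(dx.astype(np.float32))

        return _make(out.astype(np.float32), (x, w, b), backward)


class LayerNorm(Module):
    """Layer normalisation over the trailing dimension."""

    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = xhat * self.weight.data + self.bias.data
        w, b = self.weight, self.bias
        d = x.data.shape[-1]

        def backward(g):
            axes = tuple(range(g.ndim - 1))
            if w.requires_grad:
                w._accum((g * xhat).sum(axis=axes))
            if b.requires_grad:
                b._accum(g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * w.data
                t1 = dxhat.sum(axis=-1, keepdims=True)
                t2 = (dxhat * xhat).sum(axis=-1, keepdims=True)
                x._accum(((dxhat - t1 / d - xhat * t2 / d) * inv).astype(np.float32))

        return _make(out.astype(np.float32), (x, w, b), backward)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x):
        return dropout(x, self.p, self.training)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


class AdamW:
    """AdamW with decoupled weight decay (decay applied to every parameter)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
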