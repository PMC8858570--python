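"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every vector-Jacobian product is itself expressed with the primitives in
this module, so gradients are ordinary graph nodes and can be
differentiated again.  Double backprop of this kind is what the
Wasserstein gradient penalty needs: the critic loss contains the norm of
an input gradient, and its parameter gradient flows through that inner
backward pass.

The engine is deliberately small: float32 tensors, a tuple of parents
plus one VJP closure per parent, topological-order accumulation, and
pruning so that only ancestors of the requested inputs are visited.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "_parents", "_vjps")

    def __init__(self, data, parents=(), vjps=()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=DTYPE)
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, leaf={not self._parents})"

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return tensor_slice(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# shape bookkeeping helpers


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, d in enumerate(shape) if d == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# primitives


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return Tensor(
        out,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return Tensor(
        out,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def power(a: Tensor, p: float) -> Tensor:
    """Elementwise a**p for a scalar (non-tensor) exponent."""
    out = a.data**p
    return Tensor(
        out,
        parents=(a,),
        vjps=(lambda g: mul(g, mul(Tensor(np.asarray(p)), power(a, p - 1.0))),),
    )


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def tabs(a: Tensor) -> Tensor:
    sign = np.sign(a.data)
    return Tensor(np.abs(a.data), parents=(a,), vjps=(lambda g: mul(g, Tensor(sign)),))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.shape

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(shape)), shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else d for i, d in enumerate(shape))
            g = reshape(g, kshape)
        return broadcast_to(g, shape)

    return Tensor(out, parents=(a,), vjps=(vjp,))


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n)))


def broadcast_to(a: Tensor, shape) -> Tensor:
    out = np.broadcast_to(a.data, shape)
    return Tensor(out, parents=(a,), vjps=(lambda g: _unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape) -> Tensor:
    return Tensor(
        a.data.reshape(shape), parents=(a,), vjps=(lambda g: reshape(g, a.shape),)
    )


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes), parents=(a,), vjps=(lambda g: transpose(g, inv),)
    )


def mT(a: Tensor) -> Tensor:
    """Transpose of the last two axes."""
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batch broadcasting."""
    out = a.data @ b.data
    return Tensor(
        out,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(matmul(g, mT(b)), a.shape),
            lambda g: _unbroadcast(matmul(mT(a), g), b.shape),
        ),
    )


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    # slope mask is constant almost everywhere, so treating it as data is
    # the usual piecewise-linear convention
    slope = np.where(a.data > 0, 1.0, alpha).astype(DTYPE)
    return Tensor(a.data * slope, parents=(a,), vjps=(lambda g: mul(g, Tensor(slope)),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit

    out = Tensor(expit(a.data))

    def vjp(g):
        return mul(g, mul(out, add(Tensor(np.asarray(1.0)), neg(out))))

    return Tensor(out.data, parents=(a,), vjps=(vjp,))


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    offsets = np.cumsum([0] + [d.shape[axis] for d in datas])

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: tensor_slice(g, sl)

    return Tensor(
        out, parents=tuple(tensors), vjps=tuple(make_vjp(i) for i in range(len(tensors)))
    )


def tensor_slice(a: Tensor, key) -> Tensor:
    return Tensor(
        a.data[key], parents=(a,), vjps=(lambda g: embed(g, a.shape, key),)
    )


def embed(g: Tensor, shape, key) -> Tensor:
    """Scatter ``g`` into a zero tensor of ``shape`` at ``key`` (adjoint of slicing)."""
    out = np.zeros(shape, dtype=DTYPE)
    out[key] = g.data
    return Tensor(out, parents=(g,), vjps=(lambda h: tensor_slice(h, key),))


# ---------------------------------------------------------------------------
# im2col / col2im: the linear index maps behind convolution


def _conv_geometry(c, h, w, k, stride, pad):
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    return hp, wp, oh, ow


_INDEX_CACHE: dict = {}


def _patch_indices(c, h, w, k, stride, pad):
    """Flat indices into the zero-padded (c, hp, wp) image for each
    (c*k*k, oh*ow) patch position."""
    key = (c, h, w, k, stride, pad)
    cached = _INDEX_CACHE.get(key)
    if cached is not None:
        return cached
    hp, wp, oh, ow = _conv_geometry(c, h, w, k, stride, pad)
    ci = np.repeat(np.arange(c), k * k).reshape(c * k * k, 1)
    ki = np.tile(np.repeat(np.arange(k), k), c).reshape(c * k * k, 1)
    kj = np.tile(np.arange(k), c * k).reshape(c * k * k, 1)
    oi = stride * np.repeat(np.arange(oh), ow).reshape(1, oh * ow)
    oj = stride * np.tile(np.arange(ow), oh).reshape(1, oh * ow)
    rows = ki + oi
    cols = kj + oj
    flat = (ci * hp + rows) * wp + cols  # (c*k*k, oh*ow)
    _INDEX_CACHE[key] = flat
    return flat


def im2col(x: Tensor, k: int, stride: int, pad: int) -> Tensor:
    """(N, C, H, W) -> (N, C*k*k, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    hp, wp, oh, ow = _conv_geometry(c, h, w, k, stride, pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    idx = _patch_indices(c, h, w, k, stride, pad)
    cols = xp.reshape(n, -1)[:, idx]
    return Tensor(
        cols,
        parents=(x,),
        vjps=(lambda g: col2im(g, (c, h, w), k, stride, pad),),
    )


def col2im(cols: Tensor, chw, k: int, stride: int, pad: int) -> Tensor:
    """Adjoint of :func:`im2col`: scatter-add patches back to (N, C, H, W)."""
    c, h, w = chw
    n = cols.shape[0]
    hp, wp, _, _ = _conv_geometry(c, h, w, k, stride, pad)
    idx = _patch_indices(c, h, w, k, stride, pad)
    # scatter-add via one flat bincount; much faster than np.add.at
    size = c * hp * wp
    full = (np.arange(n, dtype=np.intp)[:, None] * size + idx.reshape(1, -1)).ravel()
    flat = np.bincount(full, weights=cols.data.ravel(), minlength=n * size)
    out = flat.reshape(n, c, hp, wp).astype(DTYPE)
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return Tensor(
        out,
        parents=(cols,),
        vjps=(lambda g: im2col(g, k, stride, pad),),
    )


# ---------------------------------------------------------------------------
# backward pass


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # parents before children


def grad(output: Tensor, inputs, grad_output: Tensor | None = None):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    The returned gradients are graph tensors, so they can be fed back
    into further differentiable computation (create-graph semantics).
    Inputs unreachable from ``output`` get zero gradients.
    """
    inputs = list(inputs)
    order = _toposort(output)
    wanted = {id(t) for t in inputs}
    need: dict[int, bool] = {}
    for node in order:  # parents first
        need[id(node)] = id(node) in wanted or any(
            need.get(id(p), False) for p in node._parents
        )
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape, dtype=DTYPE))
    gmap: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(order):
        g = gmap.get(id(node))
        if g is None or not need.get(id(node), False):
            continue
        for p, vjp in zip(node._parents, node._vjps):
            if not need.get(id(p), False):
                continue
            contrib = vjp(g)
            prev = gmap.get(id(p))
            gmap[id(p)] = contrib if prev is None else add(prev, contrib)
    zeros = lambda t: Tensor(np.zeros(t.shape, dtype=DTYPE))
    return [gmap.get(id(t)) or zeros(t) for t in inputs]
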