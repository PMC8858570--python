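"""Convolutional building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import (
    DTYPE,
    Tensor,
    add,
    broadcast_to,
    col2im,
    im2col,
    matmul,
    reshape,
    transpose,
)


class Parameter(Tensor):
    """A leaf tensor holding trainable weights."""

    __slots__ = ()


def init_normal(rng: np.random.Generator, shape, std: float = 0.02) -> Parameter:
    return Parameter(rng.normal(0.0, std, size=shape).astype(DTYPE))


def init_zeros(shape) -> Parameter:
    return Parameter(np.zeros(shape, dtype=DTYPE))


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """Strided 2-D convolution (cross-correlation).

    x: (N, C, H, W); w: (F, C, k, k); b: (F,).
    """
    n, c, h, w_ = x.shape
    f, c2, k, _ = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w_ + 2 * pad - k) // stride + 1
    cols = im2col(x, k, stride, pad)  # (N, C*k*k, L)
    w2 = reshape(w, (f, c * k * k))
    out = matmul(w2, cols)  # broadcast batch: (N, F, L)
    out = reshape(out, (n, f, oh, ow))
    return add(out, broadcast_to(reshape(b, (1, f, 1, 1)), out.shape))


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1
) -> Tensor:
    """Transposed convolution, the adjoint map of :func:`conv2d`.

    x: (N, C, H, W); w: (C, F, k, k); b: (F,).
    Output spatial size is (H-1)*stride - 2*pad + k.
    """
    n, c, h, w_ = x.shape
    c2, f, k, _ = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ho = (h - 1) * stride - 2 * pad + k
    wo = (w_ - 1) * stride - 2 * pad + k
    xr = reshape(x, (n, c, h * w_))
    w2 = reshape(w, (c, f * k * k))
    cols = matmul(transpose(w2), xr)  # (N, F*k*k, L)
    out = col2im(cols, (f, ho, wo), k, stride, pad)
    return add(out, broadcast_to(reshape(b, (1, f, 1, 1)), out.shape))


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, D); w: (D, M); b: (M,)."""
    out = matmul(x, w)
    return add(out, broadcast_to(reshape(b, (1, w.shape[1])), out.shape))


def pad_square(x: Tensor, target: int) -> Tensor:
    """Zero-pad the two trailing spatial dims of (N, C, H, H) up to target."""
    n, c, h, _ = x.shape
    if h == target:
        return x
    if h > target:
        raise ValueError(f"cannot pad {h} down to {target}")
    lo = (target - h) // 2
    from .autograd import embed

    key = (slice(None), slice(None), slice(lo, lo + h), slice(lo, lo + h))
    return embed(x, (n, c, target, target), key)


def crop_square(x: Tensor, target: int) -> Tensor:
    n, c, h, _ = x.shape
    if h == target:
        return x
    lo = (h - target) // 2
    return x[:, :, lo : lo + target, lo : lo + target]
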