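"""Convolution, pooling and softmax primitives for the autodiff engine.

Convolutions use an im2col/col2im formulation so the heavy lifting is a
single matmul; grouped convolution falls back to a short loop over groups.
Layouts follow the (batch, channels, height, width) convention.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, astensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "avg_pool2d",
    "global_avg_pool",
    "softmax",
    "log_softmax",
]


def _conv_out(h: int, k: int, stride: int, pad: int, dilation: int) -> int:
    return (h + 2 * pad - (k - 1) * dilation - 1) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            dilation: int = 1):
    """(B,C,H,W) -> (B, C*kh*kw, OH*OW) patch matrix (dilation-aware)."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = _conv_out(h, kh, stride, pad, dilation)
    ow = _conv_out(w, kw, stride, pad, dilation)
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, oh, ow),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            dilation: int = 1):
    """Scatter-add patch gradients back to image space (adjoint of _im2col)."""
    b, c, h, w = x_shape
    oh = _conv_out(h, kh, stride, pad, dilation)
    ow = _conv_out(w, kw, stride, pad, dilation)
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    out = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            r0, c0 = i * dilation, j * dilation
            out[:, :, r0 : r0 + oh * stride : stride,
                c0 : c0 + ow * stride : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x, weight, bias=None, stride: int = 1, pad: int = 1, groups: int = 1,
           dilation: int = 1) -> Tensor:
    """2-D convolution; ``weight`` has shape (Cout, Cin/groups, kh, kw)."""
    x, weight = astensor(x), astensor(weight)
    cout, cin_g, kh, kw = weight.shape
    b, cin, h, w = x.shape
    if groups == 1:
        cols, oh, ow = _im2col(x.data, kh, kw, stride, pad, dilation)
        wmat = weight.data.reshape(cout, -1)
        out = np.matmul(wmat, cols).reshape(b, cout, oh, ow)

        def backward(g):
            gmat = np.ascontiguousarray(g.reshape(b, cout, oh * ow))
            if weight.requires_grad:
                gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accum(gw.reshape(weight.shape))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, gmat)
                x._accum(_col2im(gcols, x.shape, kh, kw, stride, pad, dilation))

        out_t = Tensor._from_op(out, (x, weight), backward)
    else:
        xs = [x[:, g * (cin // groups) : (g + 1) * (cin // groups)] for g in range(groups)]
        ws = [
            weight[g * (cout // groups) : (g + 1) * (cout // groups)]
            for g in range(groups)
        ]
        from .autograd import concat

        out_t = concat(
            [conv2d(xg, wg, None, stride, pad, 1, dilation) for xg, wg in zip(xs, ws)],
            axis=1,
        )
    if bias is not None:
        bias = astensor(bias)
        out_t = out_t + bias.reshape(1, cout, 1, 1)
    return out_t


def conv_transpose2d(x, weight, bias=None, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; ``weight`` has shape (Cin, Cout, kh, kw).

    Output spatial size is ``(H-1)*stride + kh - 2*pad``.
    """
    x, weight = astensor(x), astensor(weight)
    cin, cout, kh, kw = weight.shape
    b, _, h, w = x.shape
    oh = (h - 1) * stride + kh - 2 * pad
    ow = (w - 1) * stride + kw - 2 * pad
    wmat = weight.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(wmat.T, x.data.reshape(b, cin, h * w))
    out = _col2im(cols, (b, cout, oh, ow), kh, kw, stride, pad)

    def backward(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, pad)
        if weight.requires_grad:
            gw = np.matmul(x.data.reshape(b, cin, h * w), gcols.transpose(0, 2, 1))
            weight._accum(gw.sum(axis=0).reshape(weight.shape))
        if x.requires_grad:
            gx = np.matmul(wmat, gcols)
            x._accum(gx.reshape(b, cin, h, w))

    out_t = Tensor._from_op(out, (x, weight), backward)
    if bias is not None:
        bias = astensor(bias)
        out_t = out_t + bias.reshape(1, cout, 1, 1)
    return out_t


def avg_pool2d(x, k: int) -> Tensor:
    """Non-overlapping k x k average pooling (H, W divisible by k)."""
    x = astensor(x)
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
    return (
        x.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))
    )


def global_avg_pool(x) -> Tensor:
    """(B,C,H,W) -> (B,C)."""
    return astensor(x).mean(axis=(2, 3))


def softmax(x, axis: int = -1) -> Tensor:
    x = astensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x, axis: int = -1) -> Tensor:
    x = astensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
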