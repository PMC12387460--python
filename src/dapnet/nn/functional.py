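"""Structured ops (convolution, pooling, normalization, losses) with manual adjoints."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, is_grad_enabled

__all__ = ["conv2d", "max_pool2d", "batch_norm2d", "softmax", "cross_entropy"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """[B,C,H,W] -> (cols [B, C*kh*kw, L], (Hout, Wout), padded input shape)."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    hout = (hp - kh) // stride + 1
    wout = (wp - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # [B,C,Hout,Wout,kh,kw]
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, hout * wout)
    return np.ascontiguousarray(cols), (hout, wout), (b, c, hp, wp)


def _col2im(cols: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            padded_shape, out_hw):
    b, c, hp, wp = padded_shape
    hout, wout = out_hw
    cols = cols.reshape(b, c, kh, kw, hout, wout)
    xp = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * hout:stride, j:j + stride * wout:stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:hp - pad, pad:wp - pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    cout, cin, kh, kw = weight.shape
    cols, (hout, wout), padded_shape = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, -1)
    out = np.einsum("ok,bkl->bol", wmat, cols, optimize=True)
    if bias is not None:
        out += bias.data[None, :, None]
    out = out.reshape(x.shape[0], cout, hout, wout)

    req = (x.requires_grad or weight.requires_grad
           or (bias is not None and bias.requires_grad))
    if not (req and is_grad_enabled()):
        return Tensor(out)

    def bw(g):
        gflat = g.reshape(g.shape[0], cout, -1)
        if weight.requires_grad:
            gw = np.einsum("bol,bkl->ok", gflat, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gflat.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("ok,bol->bkl", wmat, gflat, optimize=True)
            gx = _col2im(gcols, kh, kw, stride, padding, padded_shape, (hout, wout))
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, True, parents, bw)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    stride = stride or kernel
    b, c, _, _ = x.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    hp, wp = xd.shape[2], xd.shape[3]
    hout = (hp - kernel) // stride + 1
    wout = (wp - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xd, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride].reshape(b, c, hout, wout, kernel * kernel)
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    if not (x.requires_grad and is_grad_enabled()):
        return Tensor(out)

    def bw(g):
        gxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
        ki, kj = np.divmod(arg, kernel)
        bi, ci, oi, oj = np.indices((b, c, hout, wout), sparse=False)
        rows = oi * stride + ki
        colz = oj * stride + kj
        np.add.at(gxp, (bi, ci, rows, colz), g)
        if padding:
            gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
        x._accumulate(gxp)

    return Tensor(out, True, (x,), bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (B, H, W) per channel; mutates running stats in train mode."""
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        n = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    if not (req and is_grad_enabled()):
        return Tensor(out)

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data[None, :, None, None]
            if training:
                n = xd.shape[0] * xd.shape[2] * xd.shape[3]
                s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxh - s1 / n - xhat * s2 / n) * invstd[None, :, None, None]
            else:
                gx = gxh * invstd[None, :, None, None]
            x._accumulate(gx)

    return Tensor(out, True, (x, gamma, beta), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    out = ez / ez.sum(axis=axis, keepdims=True)

    if not (x.requires_grad and is_grad_enabled()):
        return Tensor(out)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot))

    return Tensor(out, True, (x,), bw)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``targets`` is an int class-index vector."""
    targets = np.asarray(targets)
    n, _ = logits.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), targets].mean()

    if not (logits.requires_grad and is_grad_enabled()):
        return Tensor(np.asarray(loss, dtype=logits.dtype))

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), targets] -= 1.0
        logits._accumulate(p * (g / n))

    return Tensor(np.asarray(loss, dtype=logits.dtype), True, (logits,), bw)
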