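"""Neural-network primitives (convolutions, pooling, losses) on :class:`Tensor`."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .tensor import Tensor, _make, as_tensor


def _im2col(xp: np.ndarray, KH: int, KW: int, S: int) -> np.ndarray:
    """Lower padded NCHW input to a (C*KH*KW, N*OH*OW) patch matrix.

    Channel-first column layout: each kernel offset is one block copy of
    contiguous spatial planes, which is several times faster than slicing
    a 6-D strided view.
    """
    N, C, H, W = xp.shape
    OH = (H - KH) // S + 1
    OW = (W - KW) // S + 1
    cols = np.empty((C, KH, KW, N, OH, OW), dtype=xp.dtype)
    for i in range(KH):
        for j in range(KW):
            cols[:, i, j] = xp[:, :, i:i + S * OH:S,
                               j:j + S * OW:S].transpose(1, 0, 2, 3)
    return cols.reshape(C * KH * KW, N * OH * OW)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, square stride/padding.

    Both the forward pass and both backward passes are im2col + one BLAS
    matmul: the input gradient is the zero-stuffed output gradient
    correlated with the spatially flipped, channel-transposed kernel.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    F, Cw, KH, KW = wd.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    S, P = stride, padding
    OH = (H + 2 * P - KH) // S + 1
    OW = (W + 2 * P - KW) // S + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (P, P), (P, P))) if P else xd
    cols = _im2col(xp, KH, KW, S)                        # (CKK, N*OH*OW)
    wmat = wd.reshape(F, -1)
    out = np.ascontiguousarray(
        (wmat @ cols).reshape(F, N, OH, OW).transpose(1, 0, 2, 3))
    if b is not None:
        out += b.data.reshape(1, F, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    res = _make(out, parents)
    if res._parents:

        def bw(g):
            g_mat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(
                F, N * OH * OW)
            dw = (g_mat @ cols.T).reshape(F, C, KH, KW)
            # dx: dilate g by the stride, pad by K-1-P, correlate with the
            # flipped kernel whose in/out channels are swapped
            rh = (H + 2 * P - KH) % S    # rows/cols the stride left uncovered
            rw = (W + 2 * P - KW) % S
            gd = g
            if S > 1:
                gd = np.zeros((N, F, (OH - 1) * S + 1, (OW - 1) * S + 1),
                              dtype=g.dtype)
                gd[:, :, ::S, ::S] = g
            gp = np.pad(gd, ((0, 0), (0, 0),
                             (KH - 1 - P, KH - 1 - P + rh),
                             (KW - 1 - P, KW - 1 - P + rw)))
            wflip = wd[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,KH,KW)
            gcols = _im2col(gp, KH, KW, 1)                      # (FKK, N*H*W)
            dx = np.ascontiguousarray(
                (wflip.reshape(C, -1) @ gcols).reshape(C, N, H, W).transpose(
                    1, 0, 2, 3))
            if b is not None:
                return dx, dw, g.sum(axis=(0, 2, 3))
            return dx, dw

        res._backward = bw
    return res


def conv_transpose2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed 2-D convolution; weight layout (C_in, C_out, KH, KW)."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Cw, F, KH, KW = wd.shape
    if C != Cw:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Cw}")
    S, P = stride, padding
    OH = (H - 1) * S + KH - 2 * P
    OW = (W - 1) * S + KW - 2 * P
    xmat = np.ascontiguousarray(xd.transpose(0, 2, 3, 1)).reshape(N * H * W, C)
    wmat = wd.reshape(C, F * KH * KW)
    cols = (xmat @ wmat).reshape(N, H, W, F, KH, KW).transpose(0, 3, 1, 2, 4, 5)
    outp = np.zeros((N, F, OH + 2 * P, OW + 2 * P), dtype=xd.dtype)
    for i in range(KH):
        for j in range(KW):
            outp[:, :, i:i + S * H:S, j:j + S * W:S] += cols[:, :, :, :, i, j]
    out = outp[:, :, P:P + OH, P:P + OW] if P else outp
    if b is not None:
        out = out + b.data.reshape(1, F, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    res = _make(np.ascontiguousarray(out), parents)
    if res._parents:

        def bw(g):
            gp = np.pad(g, ((0, 0), (0, 0), (P, P), (P, P))) if P else g
            gcols = np.empty((N, F, H, W, KH, KW), dtype=g.dtype)
            for i in range(KH):
                for j in range(KW):
                    gcols[:, :, :, :, i, j] = gp[:, :, i:i + S * H:S, j:j + S * W:S]
            gc_mat = np.ascontiguousarray(gcols.transpose(0, 2, 3, 1, 4, 5)).reshape(
                N * H * W, F * KH * KW)
            dx = (gc_mat @ wmat.T).reshape(N, H, W, C).transpose(0, 3, 1, 2)
            dw = (xmat.T @ gc_mat).reshape(C, F, KH, KW)
            if b is not None:
                return np.ascontiguousarray(dx), dw, g.sum(axis=(0, 2, 3))
            return np.ascontiguousarray(dx), dw

        res._backward = bw
    return res


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial size must divide by `kernel`."""
    xd = x.data
    N, C, H, W = xd.shape
    k = kernel
    if H % k or W % k:
        raise ValueError(f"max_pool2d: spatial size {H}x{W} not divisible by {k}")
    H2, W2 = H // k, W // k
    xr = xd.reshape(N, C, H2, k, W2, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H2, W2, k * k)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    res = _make(out, (x,))
    if res._parents:

        def bw(g):
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            return (gr.reshape(N, C, H2, W2, k, k).transpose(0, 1, 2, 4, 3, 5)
                    .reshape(N, C, H, W),)

        res._backward = bw
    return res


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero with probability p, scale kept units by 1/(1-p)."""
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - m
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def cross_entropy(logits: Tensor, targets: np.ndarray, axis: int = 1) -> Tensor:
    """Mean categorical cross-entropy with integer targets over `axis`."""
    ls = log_softmax(logits, axis=axis)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    np.put_along_axis(onehot, np.expand_dims(np.asarray(targets), axis), 1.0, axis=axis)
    n_positions = logits.data.size // logits.shape[axis]
    return -(ls * as_tensor(onehot)).sum() * (1.0 / n_positions)
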