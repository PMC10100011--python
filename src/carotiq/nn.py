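"""Minimal CPU building blocks for small volumetric conv nets.

Implements exactly what the segmentation network needs: valid (unpadded)
3-D convolution, ReLU, 2x2x2 max-pooling, 2x2x2 up-convolution, center
cropping, softmax cross-entropy, and the Nesterov-accelerated Adam (Nadam)
update — forward and backward, float32, single threaded.  Convolutions are
evaluated as im2col matrix products, chunked along the slice axis to bound
the scratch buffer.
"""

from __future__ import annotations

import numpy as np

_MAX_BUFFER_BYTES = 256 * 2**20  # im2col scratch cap per chunk


def _col_chunk(x: np.ndarray, z0: int, z1: int) -> np.ndarray:
    """Feature matrix (C_in*27, N) for output slices [z0, z1).

    Positions run over the *full* row/column extent of the input (the last
    two voxels of each row are junk windows wrapping into the next row);
    callers slice the valid (H-2, W-2) region out of the reshaped result.
    Each of the 27*C_in rows is one contiguous memcpy, which is what makes
    this fast.
    """
    c_in, _, h, wd = x.shape
    flat = x.reshape(c_in, -1)
    hw = h * wd
    n = (z1 - z0 - 1) * hw + (h - 3) * wd + (wd - 2)
    col = np.empty((c_in, 3, 3, 3, n), dtype=x.dtype)
    base = z0 * hw
    for i in range(3):
        for j in range(3):
            for k in range(3):
                off = base + i * hw + j * wd + k
                col[:, i, j, k, :] = flat[:, off:off + n]
    return col.reshape(c_in * 27, n)


def _z_step(x: np.ndarray) -> int:
    c, _, h, w = x.shape
    per_z = h * w * c * 27 * x.itemsize
    return max(1, _MAX_BUFFER_BYTES // max(per_z, 1))


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 3x3x3 convolution. x: (C_in, D, H, W); w: (C_out, C_in, 3, 3, 3)."""
    c_out = w.shape[0]
    _, dx, h, wd = x.shape
    d, ho, wo = dx - 2, h - 2, wd - 2
    wm = w.reshape(c_out, -1)
    y = np.empty((c_out, d, ho, wo), dtype=x.dtype)
    step = _z_step(x)
    for z0 in range(0, d, step):
        z1 = min(z0 + step, d)
        col = _col_chunk(x, z0, z1)
        yfull = np.empty((c_out, (z1 - z0) * h * wd), dtype=x.dtype)
        yfull[:, :col.shape[1]] = wm @ col  # junk at row/column wraps, sliced off
        y[:, z0:z1] = yfull.reshape(c_out, z1 - z0, h, wd)[:, :, :ho, :wo]
    return y + b[:, None, None, None]


def conv3d_backward(x: np.ndarray, w: np.ndarray, gy: np.ndarray):
    """Gradients of a valid convolution: returns (gx, gw, gb)."""
    c_out, c_in = w.shape[:2]
    d = gy.shape[1]
    _, _, h, wd = x.shape
    gb = gy.sum(axis=(1, 2, 3))
    gw_mat = np.zeros((c_out, c_in * 27), dtype=np.float64)
    step = _z_step(x)
    for z0 in range(0, d, step):
        z1 = min(z0 + step, d)
        col = _col_chunk(x, z0, z1)
        # scatter the valid gradient into the full-position layout
        gfull = np.zeros((c_out, (z1 - z0) * h * wd), dtype=x.dtype)
        gview = gfull.reshape(c_out, z1 - z0, h, wd)
        gview[:, :, :h - 2, :wd - 2] = gy[:, z0:z1]
        gw_mat += gfull[:, :col.shape[1]] @ col.T
    gw = gw_mat.reshape(w.shape).astype(x.dtype)
    # input gradient: full correlation of gy with the flipped, transposed kernel
    gy_pad = np.pad(gy, ((0, 0), (2, 2), (2, 2), (2, 2)))
    wt = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    gx = conv3d(gy_pad, wt, np.zeros(c_in, dtype=x.dtype))
    return gx, gw, gb


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(y: np.ndarray, gy: np.ndarray) -> np.ndarray:
    return np.where(y > 0, gy, 0.0)


def maxpool2(x: np.ndarray):
    """2x2x2 max pooling (even spatial extents). Returns (y, argmax_index)."""
    c, d, h, w = x.shape
    r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    r = np.ascontiguousarray(r.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
        c, d // 2, h // 2, w // 2, 8)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool2_backward(idx: np.ndarray, gy: np.ndarray, in_shape) -> np.ndarray:
    c, d, h, w = in_shape
    g = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
    np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
    g = g.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
    return np.ascontiguousarray(g).reshape(c, d, h, w)


def upconv2(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2x2 stride-2 transposed convolution. w: (C_in, C_out, 2, 2, 2)."""
    c_out = w.shape[1]
    _, d, h, wd = x.shape
    t = np.tensordot(w, x, axes=([0], [0]))  # (C_out, 2, 2, 2, D, H, W)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3)      # (C_out, D, 2, H, 2, W, 2)
    y = np.ascontiguousarray(t).reshape(c_out, 2 * d, 2 * h, 2 * wd)
    return y + b[:, None, None, None]


def upconv2_backward(x: np.ndarray, w: np.ndarray, gy: np.ndarray):
    c_out = w.shape[1]
    _, d, h, wd = x.shape
    g6 = gy.reshape(c_out, d, 2, h, 2, wd, 2).transpose(0, 2, 4, 6, 1, 3, 5)
    g6 = np.ascontiguousarray(g6)  # (C_out, 2, 2, 2, D, H, W)
    gb = gy.sum(axis=(1, 2, 3))
    gx = np.tensordot(w, g6, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
    gw = np.tensordot(x, g6, axes=([1, 2, 3], [4, 5, 6]))  # (C_in, C_out,2,2,2)
    return gx, gw, gb


def crop_center(x: np.ndarray, target_spatial) -> np.ndarray:
    """Center-crop the spatial axes of (C, D, H, W) to ``target_spatial``."""
    sl = [slice(None)]
    for have, want in zip(x.shape[1:], target_spatial):
        lo = (have - want) // 2
        sl.append(slice(lo, lo + want))
    return x[tuple(sl)]


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, target: np.ndarray,
                  class_weights=None):
    """(Optionally class-weighted) categorical cross-entropy over voxels.

    logits: (K, *spatial); target: integer class map (*spatial).
    With weights w_c the loss is sum(w_{t_v} * -log p_v) / sum(w_{t_v}),
    which reduces to the plain voxel mean when all weights are equal.
    Returns (loss, dlogits).
    """
    p = softmax(logits, axis=0)
    picked = np.take_along_axis(p, target[None], axis=0)[0]
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[None], 1.0, axis=0)
    if class_weights is None:
        n = target.size
        loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
        dlogits = (p - onehot) / n
    else:
        w = np.asarray(class_weights, dtype=p.dtype)[target]
        tot = w.sum()
        loss = float(-(w * np.log(np.clip(picked, 1e-12, None))).sum() / tot)
        dlogits = (p - onehot) * w[None] / tot
    return loss, dlogits


class Nadam:
    """Nesterov-accelerated Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1 ** t)
            v_hat = v / (1 - b2 ** t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
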