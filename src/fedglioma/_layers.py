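"""Minimal numpy neural-network primitives with explicit backpropagation.

Every forward function returns ``(output, cache)`` and has a matching
``*_backward(cache, upstream)`` returning gradients for inputs and parameters.
Shapes follow the (batch, channel, height, width) convention.  All arithmetic
is float64 so that finite-difference gradient checks are meaningful.
"""

from __future__ import annotations

import numpy as np

from .params import ParameterSet


# ---------------------------------------------------------------------------
# convolution (3x3, stride 1, zero padding "same")
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray):
    """(B, C, H, W) -> column matrix (B, C*9, H*W) for a 3x3 same conv."""
    B, C, H, Wd = x.shape
    xp = np.zeros((B, C, H + 2, Wd + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    cols = np.empty((B, C, 9, H, Wd), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            np.copyto(cols[:, :, di * 3 + dj],
                      xp[:, :, di:di + H, dj:dj + Wd])
    return cols.reshape(B, C * 9, H * Wd)


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution as one GEMM over im2col columns.

    x: (B, C, H, W); W: (O, C, 3, 3); b: (O,) -> y: (B, O, H, W)
    """
    B, C, H, Wd = x.shape
    O = W.shape[0]
    cols = _im2col(x)
    W2 = W.reshape(O, C * 9)
    y = np.matmul(W2, cols).reshape(B, O, H, Wd) + b[None, :, None, None]
    cache = (cols, W, x.shape)
    return y, cache


def conv2d_backward(cache, dy: np.ndarray):
    cols, W, xshape = cache
    B, C, H, Wd = xshape
    O = W.shape[0]
    dyf = dy.reshape(B, O, H * Wd)
    dW = np.tensordot(dyf, cols, axes=([0, 2], [0, 2])).reshape(W.shape)
    W2 = W.reshape(O, C * 9)
    dcols = np.matmul(W2.T, dyf).reshape(B, C, 9, H, Wd)
    dxp = np.zeros((B, C, H + 2, Wd + 2), dtype=dy.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + H, dj:dj + Wd] += dcols[:, :, di * 3 + dj]
    db = dy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


# ---------------------------------------------------------------------------
# activations / pooling
# ---------------------------------------------------------------------------

def relu(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(mask, dy):
    return dy * mask


def avgpool2(x):
    """2x2 average pooling, stride 2.  Spatial dims must be even."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("avgpool2 requires even spatial dimensions")
    y = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    return y, x.shape


def avgpool2_backward(shape, dy):
    B, C, H, W = shape
    dx = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0
    return dx


def maxpool2(x):
    """2x2 max pooling, stride 2; gradient flows to the first argmax of each
    block (deterministic tie-break)."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    flat = (x.reshape(B, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H // 2, W // 2, 4))
    y = flat.max(axis=-1)
    first = np.argmax(flat, axis=-1)
    sel = np.zeros(flat.shape, dtype=x.dtype)
    np.put_along_axis(sel, first[..., None], 1, axis=-1)
    return y, (sel, x.shape)


def maxpool2_backward(cache, dy):
    sel, (B, C, H, W) = cache
    dx = sel * dy[..., None]
    return (dx.reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H, W))


def global_avg_pool(x):
    """(B, C, H, W) -> (B, C) feature vectors."""
    return x.mean(axis=(2, 3)), x.shape


def global_avg_pool_backward(shape, dy):
    B, C, H, W = shape
    return np.broadcast_to(dy[:, :, None, None], shape) / (H * W)


# ---------------------------------------------------------------------------
# dense / softmax
# ---------------------------------------------------------------------------

def l2_normalize(f, eps=1e-6):
    """Per-sample scaling of feature vectors to norm sqrt(F) (unit-RMS
    elements).  Makes the fusion head scale-invariant: deep conv stacks on
    smooth images attenuate activations, and the downstream quadratic
    (bilinear) form would otherwise collapse to zero logits."""
    F = f.shape[-1]
    s = np.sqrt((f * f).sum(axis=-1, keepdims=True)) + eps
    c = np.sqrt(F)
    return c * f / s, (f, s, c)


def l2_normalize_backward(cache, dy):
    f, s, c = cache
    proj = (f * dy).sum(axis=-1, keepdims=True) / (s * s)
    return (c / s) * (dy - proj * f)


def dense(x, W, b):
    """x: (B, n_in); W: (n_in, n_out); b: (n_out,)"""
    return x @ W + b, (x, W)


def dense_backward(cache, dy):
    x, W = cache
    return dy @ W.T, x.T @ dy, dy.sum(axis=0)


def softmax(z):
    """Row-wise stable softmax."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# initializers
# ---------------------------------------------------------------------------

def he_conv(rng, c_out, c_in, k=3):
    fan_in = c_in * k * k
    return rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)


def he_dense(rng, n_in, n_out):
    return rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    """Adam on ParameterSet gradients; state is per-instance and deterministic."""

    def __init__(self, params: ParameterSet, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = params.zeros_like()
        self.v = params.zeros_like()

    def step(self, params: ParameterSet, grads: ParameterSet) -> ParameterSet:
        self.t += 1
        out = {}
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            out[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return ParameterSet(out)
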