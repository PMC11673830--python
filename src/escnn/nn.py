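"""Minimal NumPy neural-network layers with manual backprop.

Only what the sequential CNN needs: a cross-epoch 2-D convolution
(kernel height 1 or 2 over the (epoch, sample) plane), width-wise
convolutions and max-pooling, a squeeze-and-excitation gate, global
average pooling, a dense head, softmax cross-entropy and Adam.

Feature maps use the layout ``(B, L, C, W)``: batch of windows, epoch
position within the window, channels, width (time within the epoch).
All floating-point work is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "EpochConv", "ConvW", "ReLU", "MaxPoolW", "SEBlock",
    "GlobalAvgPoolW", "Dropout", "Dense", "softmax", "softmax_xent",
    "Adam",
]

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover
        raise NotImplementedError


class EpochConv(Layer):
    """First-layer conv over the (epoch, sample) plane of a window.

    Input ``(B, L, M)`` (one implicit channel); output ``(B, L, F, T)``.
    With ``kernel_h=2`` the window is padded with one zero epoch at the
    end, so position j mixes epochs j and j+1; with ``kernel_h=1`` it
    sees epoch j only.  No input gradient is computed (this layer always
    sits on the data).
    """

    def __init__(self, n_filters: int, kernel_w: int, stride: int,
                 kernel_h: int, rng: np.random.Generator):
        if kernel_h < 1:
            raise ValueError("kernel height must be >= 1")
        self.kh, self.kw, self.sw = kernel_h, kernel_w, stride
        fan_in = kernel_h * kernel_w
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (n_filters, kernel_h, kernel_w)))
        self.b = Param(np.zeros(n_filters))

    def params(self):
        return [self.W, self.b]

    def out_width(self, M: int) -> int:
        if self.kw > M:
            raise ValueError(f"kernel width {self.kw} exceeds epoch length {M}")
        return (M - self.kw) // self.sw + 1

    def forward(self, x, train: bool = False):
        B, L, M = x.shape
        T = self.out_width(M)
        if self.kh > 1:
            pad = np.zeros((B, self.kh - 1, M), dtype=F32)
            x = np.concatenate([x, pad], axis=1)
        R = L + self.kh - 1
        V = np.lib.stride_tricks.sliding_window_view(x, self.kw, axis=2)
        # one contiguous im2col per batch, cached for the backward pass;
        # a single big GEMM over all R rows beats per-offset slicing
        C = np.ascontiguousarray(V[:, :, :: self.sw, :])   # (B, R, T, kw)
        self._C, self._L, self._T = C, L, T
        Fn = self.W.value.shape[0]
        out = np.zeros((B, L, Fn, T), dtype=F32)
        flat = C.reshape(-1, self.kw)
        for h in range(self.kh):
            y = (flat @ self.W.value[:, h, :].T).reshape(B, R, T, Fn)
            out += y[:, h:h + L].transpose(0, 1, 3, 2)
        out += self.b.value[None, None, :, None]
        return out

    def backward(self, g):
        # g: (B, L, F, T); no input gradient (first layer)
        B, L, Fn, T = g.shape
        R = L + self.kh - 1
        gT = g.transpose(0, 1, 3, 2)               # (B, L, T, F)
        flatC = self._C.reshape(-1, self.kw)
        G = np.zeros((B, R, T, Fn), dtype=F32)
        for h in range(self.kh):
            G[...] = 0.0
            G[:, h:h + L] = gT
            self.W.grad[:, h, :] += (G.reshape(-1, Fn).T @ flatC)
        self.b.grad += g.sum(axis=(0, 1, 3))
        self._C = None
        return None


class ConvW(Layer):
    """Width-wise convolution: (B, L, Cin, W) -> (B, L, Cout, W-w+1)."""

    def __init__(self, c_in: int, c_out: int, width: int,
                 rng: np.random.Generator):
        self.w = width
        fan_in = c_in * width
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (c_out, c_in, width)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def out_width(self, W_in: int) -> int:
        if self.w > W_in:
            raise ValueError(f"conv width {self.w} exceeds input width {W_in}")
        return W_in - self.w + 1

    def forward(self, x, train: bool = False):
        V = np.lib.stride_tricks.sliding_window_view(x, self.w, axis=3)
        self._V, self._x_shape = V, x.shape
        out = np.einsum("blcwk,ock->blow", V, self.W.value,
                        optimize=True).astype(F32)
        return out + self.b.value[None, None, :, None]

    def backward(self, g):
        self.W.grad += np.einsum("blow,blcwk->ock", g, self._V, optimize=True)
        self.b.grad += g.sum(axis=(0, 1, 3))
        dx = np.zeros(self._x_shape, dtype=F32)
        Wout = g.shape[3]
        for k in range(self.w):
            dx[:, :, :, k:k + Wout] += np.einsum(
                "blow,oc->blcw", g, self.W.value[:, :, k], optimize=True)
        self._V = None
        return dx


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, g):
        return np.where(self._mask, g, F32(0.0))


class MaxPoolW(Layer):
    """Non-overlapping max pooling over the width axis (remainder dropped)."""

    def __init__(self, pool: int):
        self.p = max(int(pool), 1)

    def out_width(self, W_in: int) -> int:
        return max(W_in // self.p, 1)

    def forward(self, x, train: bool = False):
        p = min(self.p, x.shape[3])
        Wout = x.shape[3] // p
        xr = x[..., : Wout * p].reshape(*x.shape[:3], Wout, p)
        self._arg = xr.argmax(axis=4)
        self._shape, self._p = x.shape, p
        return xr.max(axis=4)

    def backward(self, g):
        B, L, C, W = self._shape
        p = self._p
        Wout = g.shape[3]
        dxr = np.zeros((B, L, C, Wout, p), dtype=F32)
        np.put_along_axis(dxr, self._arg[..., None], g[..., None], axis=4)
        dx = np.zeros(self._shape, dtype=F32)
        dx[..., : Wout * p] = dxr.reshape(B, L, C, Wout * p)
        return dx


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Global average pool over width -> FC (C -> C/r) -> ReLU ->
    FC (C/r -> C) -> sigmoid -> per-channel multiplicative gate in (0,1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        if channels % reduction != 0:
            raise ValueError(
                f"channels {channels} not divisible by reduction {reduction}")
        hidden = channels // reduction
        self.W1 = Param(rng.normal(0.0, np.sqrt(2.0 / channels),
                                   (hidden, channels)))
        self.b1 = Param(np.zeros(hidden))
        self.W2 = Param(rng.normal(0.0, np.sqrt(2.0 / hidden),
                                   (channels, hidden)))
        self.b2 = Param(np.zeros(channels))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, train: bool = False):
        z = x.mean(axis=3)                         # (B, L, C)
        a_pre = z @ self.W1.value.T + self.b1.value
        a = np.maximum(a_pre, 0.0)
        g_pre = a @ self.W2.value.T + self.b2.value
        gate = _sigmoid(g_pre)                     # (B, L, C)
        self._cache = (x, z, a_pre, a, gate)
        return x * gate[..., None]

    def backward(self, g):
        x, z, a_pre, a, gate = self._cache
        dx1 = g * gate[..., None]
        dgate = (g * x).sum(axis=3)
        dg_pre = dgate * gate * (1.0 - gate)
        n = dg_pre.reshape(-1, dg_pre.shape[-1])
        an = a.reshape(-1, a.shape[-1])
        self.W2.grad += n.T @ an
        self.b2.grad += n.sum(axis=0)
        da = dg_pre @ self.W2.value
        da_pre = np.where(a_pre > 0, da, 0.0)
        m = da_pre.reshape(-1, da_pre.shape[-1])
        zn = z.reshape(-1, z.shape[-1])
        self.W1.grad += m.T @ zn
        self.b1.grad += m.sum(axis=0)
        dz = da_pre @ self.W1.value
        dx2 = np.broadcast_to(dz[..., None] / x.shape[3], x.shape)
        self._cache = None
        return (dx1 + dx2).astype(F32)


class GlobalAvgPoolW(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=3)

    def backward(self, g):
        B, L, C, W = self._shape
        return np.broadcast_to(g[..., None] / W, self._shape).astype(F32)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense(Layer):
    """Shared per-position linear map: (B, L, Din) -> (B, L, Dout).

    ``scale`` overrides the He weight scale; a classifier head uses a
    small scale so the untrained network starts near the uniform
    distribution over classes.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        sd = np.sqrt(2.0 / d_in) if scale is None else scale
        self.W = Param(rng.normal(0.0, sd, (d_out, d_in)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        g2 = g.reshape(-1, g.shape[-1])
        x2 = self._x.reshape(-1, self._x.shape[-1])
        self.W.grad += g2.T @ x2
        self.b.grad += g2.sum(axis=0)
        dx = g @ self.W.value
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray,
                 class_weights: np.ndarray | None = None):
    """Mean cross-entropy over all (window, position) pairs.

    Returns ``(loss, dlogits)``.
    """
    p = softmax(logits.astype(np.float64))
    B, L, C = p.shape
    flat_p = p.reshape(-1, C)
    flat_y = labels.reshape(-1)
    w = np.ones(flat_y.size) if class_weights is None \
        else np.asarray(class_weights, dtype=float)[flat_y]
    picked = np.clip(flat_p[np.arange(flat_y.size), flat_y], 1e-12, None)
    loss = float((w * -np.log(picked)).sum() / w.sum())
    d = flat_p.copy()
    d[np.arange(flat_y.size), flat_y] -= 1.0
    d *= (w / w.sum())[:, None]
    return loss, d.reshape(B, L, C).astype(F32)


class Adam:
    """Adaptive-moment gradient descent over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= (self.lr * (m / bc1)
                        / (np.sqrt(v / bc2) + self.eps)).astype(F32)
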