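"""Layer implementations with explicit backward passes.

All activations are NCHW float arrays.  Convolutions are stride-1
"same" correlations realised through im2col + matmul; the input gradient
of a convolution is itself a convolution with the channel-transposed,
spatially flipped kernel.  Every layer exposes ``params()`` for the
optimizer and caches forward intermediates for one backward call.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError, DimensionError


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base layer: parameter access plus a forward/backward pair."""

    def params(self) -> List[Parameter]:
        return []

    def buffers(self) -> dict:
        return {}

    def forward(self, x, mode: str = "train", rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int):
    """(N,C,H,W) -> (N*H*W, C*k*k) column matrix for a same-padded window."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


def conv2d_same(x: np.ndarray, weight: np.ndarray, bias=None):
    """Stride-1 same-padding correlation. Returns (y, cols) with cols cached
    for the weight gradient."""
    n, c, h, w = x.shape
    o, ci, k, _ = weight.shape
    if ci != c:
        raise DimensionError(f"conv expects {ci} input channels, got {c}")
    cols = _im2col(x, k)
    y = cols @ weight.reshape(o, -1).T
    if bias is not None:
        y += bias
    return y.reshape(n, h, w, o).transpose(0, 3, 1, 2), cols


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "conv"):
        if kernel % 2 != 1:
            raise ConfigurationError("only odd kernels supported")
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialization (ELU/ReLU family)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(dtype),
            name=f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype), name=f"{name}.bias")
        self.kernel = kernel
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, mode="train", rng=None):
        y, cols = conv2d_same(x, self.weight.data, self.bias.data)
        self._cols = cols
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        o = self.weight.data.shape[0]
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, o)
        self.weight.grad = (dy2.T @ self._cols).reshape(self.weight.data.shape)
        self.bias.grad = dy2.sum(axis=0)
        w_flip = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = conv2d_same(dy, np.ascontiguousarray(w_flip))
        self._cols = None
        return dx


class ConvTranspose2x2(Layer):
    """2×2 stride-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "up"):
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Parameter(
            rng.normal(0.0, std, size=(in_ch, out_ch, 2, 2)).astype(dtype),
            name=f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype), name=f"{name}.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, mode="train", rng=None):
        self._x = x
        n, c, h, w = x.shape
        o = self.weight.data.shape[1]
        y = np.einsum("ncij,coab->noiajb", x, self.weight.data, optimize=True)
        y = y.reshape(n, o, 2 * h, 2 * w) + self.bias.data[None, :, None, None]
        return y

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        o = self.weight.data.shape[1]
        dy6 = dy.reshape(n, o, h, 2, w, 2)
        self.weight.grad = np.einsum("ncij,noiajb->coab", x, dy6, optimize=True)
        self.bias.grad = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("noiajb,coab->ncij", dy6, self.weight.data, optimize=True)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with exposable running statistics.

    The running mean/variance are plain buffers so that adaptive transfer
    can rewrite them without touching the trainable scale/shift.  In
    ``adapt`` mode batch statistics are both used for normalization and
    appended to ``adapt_stats`` for the caller to pool.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn"):
        self.gamma = Parameter(np.ones(ch, dtype=dtype), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(ch, dtype=dtype), name=f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.adapt_stats: list = []
        #: when set, train mode normalizes with the stored running
        #: statistics and does not update them (small-sample fine-tuning)
        self.stats_frozen = False
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def forward(self, x, mode="train", rng=None):
        if mode == "train" and self.stats_frozen:
            mode = "eval"
        if mode in ("train", "adapt"):
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if mode == "train":
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                    self.running_mean.dtype)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(
                    self.running_var.dtype)
            else:
                count = x.shape[0] * x.shape[2] * x.shape[3]
                self.adapt_stats.append((mu.copy(), var.copy(), count))
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, mode)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, inv, mode = self._cache
        self.gamma.grad = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if mode in ("eval", "mc"):
            dx = dxhat * inv[None, :, None, None]
        else:
            m = dy.shape[0] * dy.shape[2] * dy.shape[3]
            s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._y = None

    def forward(self, x, mode="train", rng=None):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        dx = dy * np.where(y > 0, 1.0, y + self.alpha)
        self._y = None
        return dx


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, mode="train", rng=None):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        self._y = None
        return dy * y * (1.0 - y)


class MaxPool2x2(Layer):
    def __init__(self):
        self._mask = None
        self._shape = None

    def forward(self, x, mode="train", rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise DimensionError("max-pool requires even spatial extent")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._mask = idx
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._mask[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._mask = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class SpatialDropout2d(Layer):
    """Channel-wise (spatial) dropout: whole feature maps are zeroed.

    Active in ``mc`` mode always; in ``train`` mode only when
    ``train_active`` is set.  Keeping ordinary training deterministic
    means the batch-norm running statistics describe the same activation
    distribution the network sees at evaluation time — the fixed point
    that statistic-transfer adaptation relies on.
    """

    def __init__(self, p: float, train_active: bool = False):
        if not 0.0 <= p < 1.0:
            raise ConfigurationError("dropout rate must lie in [0, 1)")
        self.p = p
        self.train_active = train_active
        self._mask = None

    def forward(self, x, mode="train", rng=None):
        inactive = (mode in ("eval", "adapt")
                    or (mode == "train" and not self.train_active))
        if self.p == 0.0 or inactive:
            self._mask = None
            return x
        if rng is None:
            raise ConfigurationError("dropout in train/mc mode needs an rng")
        keep = (rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p)
        mask = keep.astype(x.dtype) / (1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class NonLocalBlock(Layer):
    """Embedded-Gaussian nonlocal attention with residual connection.

    Query/key/value are 1×1 projections to ``ch // 2`` channels; the
    affinity between positions i and j is softmax_j(θ(x_i)ᵀφ(x_j)) over all
    spatial positions, so each row of the affinity matrix is a
    distribution over the feature grid.  The output projection is
    zero-initialized, making the block an identity at the start of
    training.  The most recent affinity is kept in ``last_affinity`` for
    attention-map visualization.
    """

    def __init__(self, ch: int, rng: np.random.Generator, dtype=np.float32,
                 name: str = "nonlocal"):
        inter = max(1, ch // 2)
        std = np.sqrt(1.0 / ch)
        self.w_theta = Parameter(rng.normal(0, std, (inter, ch)).astype(dtype),
                                 name=f"{name}.theta")
        self.w_phi = Parameter(rng.normal(0, std, (inter, ch)).astype(dtype),
                               name=f"{name}.phi")
        self.w_g = Parameter(rng.normal(0, std, (inter, ch)).astype(dtype),
                             name=f"{name}.g")
        self.w_z = Parameter(np.zeros((ch, inter), dtype=dtype), name=f"{name}.z")
        self.b_z = Parameter(np.zeros(ch, dtype=dtype), name=f"{name}.z_bias")
        self.inter = inter
        self.last_affinity: Optional[np.ndarray] = None
        self._cache = None

    def params(self):
        return [self.w_theta, self.w_phi, self.w_g, self.w_z, self.b_z]

    def forward(self, x, mode="train", rng=None):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        t = np.einsum("ic,ncp->nip", self.w_theta.data, xf, optimize=True)
        ph = np.einsum("ic,ncp->nip", self.w_phi.data, xf, optimize=True)
        g = np.einsum("ic,ncp->nip", self.w_g.data, xf, optimize=True)
        logits = np.einsum("nip,niq->npq", t, ph, optimize=True)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        att = e / e.sum(axis=-1, keepdims=True)  # row-stochastic (N,P,P)
        y = np.einsum("npq,niq->nip", att, g, optimize=True)
        z = np.einsum("ci,nip->ncp", self.w_z.data, y, optimize=True) \
            + self.b_z.data[None, :, None]
        self.last_affinity = att
        self._cache = (x, xf, t, ph, g, att, y)
        return x + z.reshape(n, c, h, w)

    def backward(self, dy):
        x, xf, t, ph, g, att, y = self._cache
        n, c, h, w = x.shape
        dz = dy.reshape(n, c, h * w)
        self.b_z.grad = dz.sum(axis=(0, 2))
        self.w_z.grad = np.einsum("ncp,nip->ci", dz, y, optimize=True)
        dyy = np.einsum("ci,ncp->nip", self.w_z.data, dz, optimize=True)
        datt = np.einsum("nip,niq->npq", dyy, g, optimize=True)
        dg = np.einsum("npq,nip->niq", att, dyy, optimize=True)
        # softmax backward per row
        dlog = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dt = np.einsum("npq,niq->nip", dlog, ph, optimize=True)
        dph = np.einsum("npq,nip->niq", dlog, t, optimize=True)
        self.w_theta.grad = np.einsum("nip,ncp->ic", dt, xf, optimize=True)
        self.w_phi.grad = np.einsum("nip,ncp->ic", dph, xf, optimize=True)
        self.w_g.grad = np.einsum("nip,ncp->ic", dg, xf, optimize=True)
        dxf = (
            np.einsum("ic,nip->ncp", self.w_theta.data, dt, optimize=True)
            + np.einsum("ic,nip->ncp", self.w_phi.data, dph, optimize=True)
            + np.einsum("ic,nip->ncp", self.w_g.data, dg, optimize=True)
        )
        self._cache = None
        return dy + dxf.reshape(n, c, h, w)

    def param_count(self) -> int:
        return sum(p.size for p in self.params())
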