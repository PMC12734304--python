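"""Compact NumPy engine for small trainable 3D CNNs.

Implements exactly the primitives the volumetric classifier needs — grouped /
dilated 3D convolution, batch normalisation, ReLU, global average pooling and
a linear head — each with an explicit forward and backward pass, plus an SGD
optimiser with momentum/weight decay and a reduce-on-plateau LR schedule.

Conventions
-----------
* Feature maps are ``float32`` arrays of shape ``(N, C, D, H, W)``.
* Convolutions use zero padding; ``padding="same"`` resolves to
  ``((k - 1) * dilation) // 2``, which preserves (or halves, at stride 2)
  the spatial extent for odd kernels.
* Depthwise convolutions (``groups == c_in == c_out``) take a dedicated
  shifted-slice code path that avoids the im2col memory blow-up.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: forward/backward plus recursive parameter discovery."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self):
        return ()

    def named_params(self, prefix: str = ""):
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                yield (f"{prefix}{name}", attr)
        for i, child in enumerate(self.children()):
            cname = getattr(child, "name", None) or f"{type(child).__name__.lower()}{i}"
            yield from child.named_params(prefix=f"{prefix}{cname}.")

    def params(self):
        for _, p in self.named_params():
            yield p

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


def conv_out_size(n: int, k: int, stride: int, pad: int, dilation: int) -> int:
    eff = (k - 1) * dilation + 1
    return (n + 2 * pad - eff) // stride + 1


def _resolve_padding(padding, k: int, dilation: int) -> int:
    if padding == "same":
        return ((k - 1) * dilation) // 2
    return int(padding)


class Conv3d(Layer):
    """Grouped, strided, dilated 3D convolution (cross-correlation).

    Weight shape is ``(c_out, c_in // groups, k, k, k)``.  Bias is optional
    and disabled throughout the network (every conv is followed by BN).
    """

    def __init__(self, c_in, c_out, k, stride=1, padding="same", dilation=1,
                 groups=1, bias=False, rng=None):
        if c_in % groups or c_out % groups:
            raise ValueError(
                f"channel counts ({c_in}->{c_out}) not divisible by groups={groups}")
        self.c_in, self.c_out, self.k = int(c_in), int(c_out), int(k)
        self.stride, self.dilation, self.groups = int(stride), int(dilation), int(groups)
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        self.pad = _resolve_padding(padding, self.k, self.dilation)
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = (c_in // groups) * k ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in // groups, k, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    # profiling hooks -------------------------------------------------
    def out_shape(self, in_shape):
        c, d, h, w = in_shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, found {c}")
        s, p, dl, k = self.stride, self.pad, self.dilation, self.k
        return (self.c_out, conv_out_size(d, k, s, p, dl),
                conv_out_size(h, k, s, p, dl), conv_out_size(w, k, s, p, dl))

    def flops(self, in_shape):
        _, do, ho, wo = self.out_shape(in_shape)
        return 2 * do * ho * wo * (self.c_in // self.groups) * self.k ** 3 * self.c_out

    # forward / backward ---------------------------------------------
    def _depthwise(self):
        return self.groups == self.c_in and self.c_in == self.c_out

    def forward(self, x, training=False):
        N, C, D, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, found {C}")
        s, p, dl, k = self.stride, self.pad, self.dilation, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        Do = conv_out_size(D, k, s, p, dl)
        Ho = conv_out_size(H, k, s, p, dl)
        Wo = conv_out_size(W, k, s, p, dl)
        if min(Do, Ho, Wo) < 1:
            raise ValueError(f"kernel does not fit input of shape {x.shape}")
        w = self.weight.data
        if self._depthwise():
            out = np.zeros((N, C, Do, Ho, Wo), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        xi = xp[:, :,
                                i * dl: i * dl + s * (Do - 1) + 1: s,
                                j * dl: j * dl + s * (Ho - 1) + 1: s,
                                l * dl: l * dl + s * (Wo - 1) + 1: s]
                        out += w[:, 0, i, j, l][None, :, None, None, None] * xi
            self._cache = ("dw", xp, x.shape, (Do, Ho, Wo))
        else:
            win = sliding_window_view(
                xp, ((k - 1) * dl + 1,) * 3, axis=(2, 3, 4)
            )[:, :, ::s, ::s, ::s, ::dl, ::dl, ::dl]
            # win: (N, C, Do, Ho, Wo, k, k, k)
            cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
                N * Do * Ho * Wo, C * k ** 3).astype(np.float32, copy=True)
            g, cg, cog = self.groups, self.c_in // self.groups, self.c_out // self.groups
            wmat = w.reshape(g, cog, cg * k ** 3)
            out = np.empty((N * Do * Ho * Wo, self.c_out), dtype=np.float32)
            step = cg * k ** 3
            for gi in range(g):
                out[:, gi * cog:(gi + 1) * cog] = cols[:, gi * step:(gi + 1) * step] @ wmat[gi].T
            out = out.reshape(N, Do, Ho, Wo, self.c_out).transpose(0, 4, 1, 2, 3)
            out = np.ascontiguousarray(out)
            self._cache = ("gemm", cols, x.shape, (Do, Ho, Wo))
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, dy):
        mode, cached, x_shape, (Do, Ho, Wo) = self._cache
        N, C, D, H, W = x_shape
        s, p, dl, k = self.stride, self.pad, self.dilation, self.k
        w = self.weight.data
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        if mode == "dw":
            xp = cached
            dxp = np.zeros_like(xp)
            dw = self.weight.grad
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        sl = (slice(None), slice(None),
                              slice(i * dl, i * dl + s * (Do - 1) + 1, s),
                              slice(j * dl, j * dl + s * (Ho - 1) + 1, s),
                              slice(l * dl, l * dl + s * (Wo - 1) + 1, s))
                        dw[:, 0, i, j, l] += np.einsum("ncdhw,ncdhw->c", xp[sl], dy)
                        dxp[sl] += w[:, 0, i, j, l][None, :, None, None, None] * dy
            dx = dxp[:, :, p:p + D, p:p + H, p:p + W] if p else dxp
            return np.ascontiguousarray(dx)
        cols = cached
        g, cg, cog = self.groups, self.c_in // self.groups, self.c_out // self.groups
        dyf = dy.transpose(0, 2, 3, 4, 1).reshape(N * Do * Ho * Wo, self.c_out)
        wmat = w.reshape(g, cog, cg * k ** 3)
        dcols = np.empty_like(cols)
        step = cg * k ** 3
        for gi in range(g):
            dyg = dyf[:, gi * cog:(gi + 1) * cog]
            self.weight.grad.reshape(g, cog, step)[gi] += dyg.T @ cols[:, gi * step:(gi + 1) * step]
            dcols[:, gi * step:(gi + 1) * step] = dyg @ wmat[gi]
        dwin = dcols.reshape(N, Do, Ho, Wo, C, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :,
                        i * dl: i * dl + s * (Do - 1) + 1: s,
                        j * dl: j * dl + s * (Ho - 1) + 1: s,
                        l * dl: l * dl + s * (Wo - 1) + 1: s] += dwin[..., i, j, l]
        dx = dxp[:, :, p:p + D, p:p + H, p:p + W] if p else dxp
        return np.ascontiguousarray(dx)


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (N, D, H, W).

    Training mode normalises with batch statistics (biased variance) and
    updates running statistics with momentum; eval mode uses the running
    statistics.  ``gamma`` is the channel scale consumed by the pruning rule.
    """

    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.c, self.eps, self.momentum = int(c), float(eps), float(momentum)
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def out_shape(self, in_shape):
        return in_shape

    def flops(self, in_shape):
        return 0

    def forward(self, x, training=False):
        if training:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
            unbiased = var * n / max(n - 1, 1)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32, copy=False)
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(np.float32, copy=False)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = (self.gamma.data[None, :, None, None, None] * xhat
               + self.beta.data[None, :, None, None, None])
        self._cache = (xhat, inv, training)
        return out.astype(np.float32, copy=False)

    def backward(self, dy):
        xhat, inv, training = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += np.einsum("ncdhw,ncdhw->c", dy, xhat)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        if not training:
            return (dy * g * inv[None, :, None, None, None]).astype(np.float32, copy=False)
        n = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return (dx * inv[None, :, None, None, None]).astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32, copy=False)

    def out_shape(self, in_shape):
        return in_shape

    def flops(self, in_shape):
        return 0


class GlobalAvgPool3d(Layer):
    """(N, C, D, H, W) -> (N, C) spatial mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32, copy=False)

    def backward(self, dy):
        N, C, D, H, W = self._shape
        scale = 1.0 / (D * H * W)
        return (np.broadcast_to(dy[:, :, None, None, None], self._shape) * scale
                ).astype(np.float32, copy=False)

    def out_shape(self, in_shape):
        return (in_shape[0],)

    def flops(self, in_shape):
        return 0


class Linear(Layer):
    def __init__(self, m, n, bias=True, rng=None, count_in_flops=True):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.m, self.n = int(m), int(n)
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / m), size=(n, m)))
        self.bias = Param(np.zeros(n)) if bias else None
        self.count_in_flops = count_in_flops

    def forward(self, x, training=False):
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out.astype(np.float32, copy=False)

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.data).astype(np.float32, copy=False)

    def out_shape(self, in_shape):
        return (self.n,)

    def flops(self, in_shape):
        return 2 * self.m * self.n if self.count_in_flops else 0


class Sequential(Layer):
    def __init__(self, layers, name=None):
        self.layers = list(layers)
        if name:
            self.name = name

    def children(self):
        return self.layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def flops(self, in_shape):
        total = 0
        for layer in self.layers:
            total += layer.flops(in_shape)
            in_shape = layer.out_shape(in_shape)
        return total


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def label_smoothing_loss(scores: np.ndarray, labels: np.ndarray, epsilon: float = 0.1):
    """Mean label-smoothed cross-entropy and its gradient w.r.t. scores.

    The target distribution mixes the one-hot label with a uniform component:
    ``q = (1 - eps) * onehot + eps / K``.  ``eps = 0`` recovers plain CE.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon}")
    scores = np.asarray(scores, dtype=np.float64)
    n, k = scores.shape
    z = scores - scores.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    q = np.full((n, k), epsilon / k)
    q[np.arange(n), labels] += 1.0 - epsilon
    loss = -(q * logp).sum(axis=1).mean()
    dscores = (np.exp(logp) - q) / n
    return float(loss), dscores.astype(np.float32, copy=False)


class SGD:
    """SGD with momentum and (coupled) weight decay, PyTorch-style update:

    ``v = mu * v + grad + wd * p;  p -= lr * v``
    """

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = float(lr), float(momentum), float(weight_decay)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` after ``patience`` non-improving epochs.

    Min mode with relative threshold: an epoch improves when
    ``metric < best * (1 - threshold)``.
    """

    def __init__(self, optimizer, factor=0.1, patience=10, threshold=1e-4, min_lr=0.0):
        self.opt = optimizer
        self.factor, self.patience = float(factor), int(patience)
        self.threshold, self.min_lr = float(threshold), float(min_lr)
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float):
        if metric < self.best * (1.0 - self.threshold):
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
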