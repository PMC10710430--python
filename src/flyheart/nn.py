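"""Minimal neural-network layer library on numpy.

Implements exactly the layers the FlyNet segmentation model needs —
2-D convolution, convolutional LSTM, batch normalization, leaky ReLU,
max pooling, strided transposed convolution, sigmoid — each with an
explicit backward pass, plus the Adam optimizer.

Conventions
-----------
* Per-frame tensors are ``(N, C, H, W)`` where ``N`` may fold batch and
  time together; sequence tensors are ``(B, T, C, H, W)``.
* ``layer.forward(x, training)`` returns ``(y, cache)``;
  ``layer.backward(dy, cache)`` returns ``dx`` and accumulates parameter
  gradients in place, so weight sharing across time steps needs no extra
  machinery.
* Gradients accumulate until :func:`zero_grads` is called.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, training=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


def _sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv2d(Layer):
    """Same-padded 2-D convolution via im2col + GEMM.

    Weight is stored as a ``(C_in * k * k, C_out)`` matrix so forward and
    backward are single matrix products.
    """

    def __init__(self, c_in, c_out, k=3, rng=None, init="he", dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        if init == "he":
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(fan_in, c_out))
        else:  # glorot uniform
            lim = np.sqrt(6.0 / (fan_in + c_out))
            w = rng.uniform(-lim, lim, size=(fan_in, c_out))
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        self.w = Param(w.astype(dtype), "conv_w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "conv_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        # (N, C, H, W, k, k) view -> (N*H*W, C*k*k)
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * h * w, c * k * k)
        y = cols @ self.w.value + self.b.value
        y = y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(y), (cols, (n, c, h, w))

    def backward(self, dy, cache):
        cols, (n, c, h, w) = cache
        k, p = self.k, self.pad
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.w.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.w.value.T).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for a in range(k):
            for bb in range(k):
                dxp[:, :, a : a + h, bb : bb + w] += dcols[:, :, :, :, a, bb].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvLSTM2d(Layer):
    """Convolutional LSTM over the time axis.

    Gate pre-activations are one 3x3 convolution of ``concat(x_t, h_prev)``
    producing ``4 * hidden`` channels (input, forget, cell, output order).
    The forget-gate bias starts at 1 so early training does not wash out
    state. Processes forward in time only; initial state is zero.
    """

    def __init__(self, c_in, c_hidden, k=3, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_hidden = c_in, c_hidden
        self.conv = Conv2d(c_in + c_hidden, 4 * c_hidden, k, rng=rng, init="glorot", dtype=dtype)
        self.conv.b.value[c_hidden : 2 * c_hidden] = 1.0

    def params(self):
        return self.conv.params()

    def forward(self, x, training=True):
        b, t, c, h, w = x.shape
        ch = self.c_hidden
        hs = np.zeros((b, t, ch, h, w), dtype=x.dtype)
        h_t = np.zeros((b, ch, h, w), dtype=x.dtype)
        c_t = np.zeros((b, ch, h, w), dtype=x.dtype)
        steps = []
        for ti in range(t):
            z_in = np.concatenate([x[:, ti], h_t], axis=1)
            z, conv_cache = self.conv.forward(z_in, training)
            i = _sigmoid(z[:, :ch])
            f = _sigmoid(z[:, ch : 2 * ch])
            g = np.tanh(z[:, 2 * ch : 3 * ch])
            o = _sigmoid(z[:, 3 * ch :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            hs[:, ti] = h_t
            steps.append((conv_cache, i, f, g, o, c_prev, tc))
        return hs, (steps, x.shape)

    def backward(self, dhs, cache):
        steps, (b, t, c, h, w) = cache
        ch = self.c_hidden
        dx = np.zeros((b, t, c, h, w), dtype=dhs.dtype)
        dh_next = np.zeros((b, ch, h, w), dtype=dhs.dtype)
        dc_next = np.zeros_like(dh_next)
        for ti in range(t - 1, -1, -1):
            conv_cache, i, f, g, o, c_prev, tc = steps[ti]
            dh = dhs[:, ti] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dzin = self.conv.backward(dz, conv_cache)
            dx[:, ti] = dzin[:, : self.c_in]
            dh_next = dzin[:, self.c_in :]
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=DEFAULT_DTYPE):
        self.gamma = Param(np.ones(c, dtype=dtype), "bn_gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn_beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=True):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * invstd[:, None, None]
        y = self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]
        return y, (xhat, invstd, training)

    def backward(self, dy, cache):
        xhat, invstd, training = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None]
        if not training:
            return dxhat * invstd[:, None, None]
        n, c, h, w = dy.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return (invstd[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, training=True):
        neg = x < 0
        y = np.where(neg, self.slope * x, x)
        return y, neg

    def backward(self, dy, neg):
        return np.where(neg, self.slope * dy, dy)


class Sigmoid(Layer):
    def forward(self, x, training=True):
        y = _sigmoid(x)
        return y, y

    def backward(self, dy, y):
        return dy * y * (1.0 - y)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2. Ties break toward the first element."""

    def forward(self, x, training=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return y, (idx, x.shape)

    def backward(self, dy, cache):
        idx, (n, c, h, w) = cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in, c_out, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng()
        fan_in = c_in * 4
        std = np.sqrt(2.0 / fan_in)
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, std, size=(c_in, c_out, 2, 2)).astype(dtype), "upconv_w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "upconv_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        n, c, h, w = x.shape
        y = np.einsum("ncij,cfab->nfiajb", x, self.w.value, optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w) + self.b.value[:, None, None]
        return y, x

    def backward(self, dy, x):
        n, c, h, w = x.shape
        dyr = dy.reshape(n, self.c_out, h, 2, w, 2)
        self.w.grad += np.einsum("ncij,nfiajb->cfab", x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("nfiajb,cfab->ncij", dyr, self.w.value, optimize=True)


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
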