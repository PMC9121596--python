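"""Minimal NumPy neural-network engine.

Implements exactly the layer vocabulary the W-Net / DCGAN / LSTM models
need: 2-D convolution (arbitrary stride, same/valid padding), transposed
convolution, 2x2 max pooling, dense layers, dropout, batch normalization,
ReLU / LeakyReLU / sigmoid activations and a single-layer LSTM — each with
a hand-written backward pass — plus Adam and SGD-with-momentum optimizers
and Xavier-uniform initialization.

Images are NHWC float arrays.  All layers expose ``forward(x, train, rng)``
and ``backward(dout)``; parameters and their gradients live in ``params``
and ``grads`` dicts on each layer so optimizers can walk a model uniformly.

This module exists because the toolkit must run on a plain scientific
Python stack with no deep-learning framework available; the convolutions
are expressed as a handful of BLAS matmuls (one per kernel tap) so training
small models on a single CPU stays fast.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "MaxPool2x2",
    "Dense",
    "Flatten",
    "Reshape",
    "Dropout",
    "BatchNorm",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "LSTM",
    "Sequential",
    "xavier_uniform_bound",
    "xavier_uniform",
    "AdamOptimizer",
    "MomentumOptimizer",
]

DTYPE = np.float32


# ---------------------------------------------------------------------------
# initialization


def xavier_uniform_bound(fan_in: int, fan_out: int) -> float:
    """Glorot/Xavier uniform bound x = sqrt(6 / (fan_in + fan_out))."""
    if fan_in <= 0 or fan_out <= 0:
        raise ValueError("fan_in and fan_out must be positive")
    return float(np.sqrt(6.0 / (fan_in + fan_out)))


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator):
    """Draw i.i.d. U[-x, x] weights with the Xavier bound for the given fans."""
    x = xavier_uniform_bound(fan_in, fan_out)
    return rng.uniform(-x, x, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: parameter/grad dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _pad_amounts(in_size: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    """Total (before, after) zero padding for one spatial axis."""
    if padding == "valid":
        return 0, 0
    # 'same': output size = ceil(in/stride)
    out = -(-in_size // stride)
    total = max((out - 1) * stride + k - in_size, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution, NHWC, bias included.

    Implemented as one matmul per kernel tap: for each (di, dj) offset the
    padded input is sliced with the stride and multiplied by W[di, dj],
    which keeps memory flat and leans on BLAS.
    """

    def __init__(self, in_channels, out_channels, kernel=3, stride=1,
                 padding="same", seed=0):
        super().__init__()
        self.cin, self.cout = int(in_channels), int(out_channels)
        self.k = int(kernel)
        self.stride = int(stride)
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        rng = np.random.default_rng(seed)
        fan_in = self.k * self.k * self.cin
        fan_out = self.k * self.k * self.cout
        self.params["W"] = xavier_uniform(
            (self.k, self.k, self.cin, self.cout), fan_in, fan_out, rng)
        self.params["b"] = np.zeros(self.cout, dtype=DTYPE)

    def _geometry(self, h, w):
        pt, pb = _pad_amounts(h, self.k, self.stride, self.padding)
        pl, pr = _pad_amounts(w, self.k, self.stride, self.padding)
        oh = (h + pt + pb - self.k) // self.stride + 1
        ow = (w + pl + pr - self.k) // self.stride + 1
        return pt, pb, pl, pr, oh, ow

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, h, w, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        pt, pb, pl, pr, oh, ow = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        W, b = self.params["W"], self.params["b"]
        s = self.stride
        out = np.zeros((n, oh, ow, self.cout), dtype=DTYPE)
        flat = out.reshape(-1, self.cout)
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, di:di + s * oh:s, dj:dj + s * ow:s, :]
                flat += patch.reshape(-1, self.cin) @ W[di, dj]
        out += b
        self._cache = (xp, x.shape, (pt, pb, pl, pr, oh, ow))
        return out

    def backward(self, dout):
        xp, xshape, geom = self._cache
        pt, pb, pl, pr, oh, ow = geom
        n, h, w, _ = xshape
        s = self.stride
        W = self.params["W"]
        dout = np.ascontiguousarray(dout, dtype=DTYPE)
        dflat = dout.reshape(-1, self.cout)
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, di:di + s * oh:s, dj:dj + s * ow:s, :]
                dW[di, dj] = patch.reshape(-1, self.cin).T @ dflat
                dxp[:, di:di + s * oh:s, dj:dj + s * ow:s, :] += (
                    dflat @ W[di, dj].T).reshape(n, oh, ow, self.cin)
        self.grads["W"] = dW
        self.grads["b"] = dflat.sum(axis=0)
        return dxp[:, pt:pt + h, pl:pl + w, :]


class ConvTranspose2D(Layer):
    """Transposed (fractionally strided) convolution, NHWC, bias included.

    Output spatial size is (in-1)*stride - 2*pad + kernel; with kernel 4,
    stride 2, pad 1 this exactly doubles the input, the standard DCGAN
    upsampling step.  Forward is the adjoint (scatter) of Conv2D's gather.
    """

    def __init__(self, in_channels, out_channels, kernel=4, stride=2, pad=1,
                 seed=0):
        super().__init__()
        self.cin, self.cout = int(in_channels), int(out_channels)
        self.k, self.stride, self.pad = int(kernel), int(stride), int(pad)
        rng = np.random.default_rng(seed)
        fan_in = self.k * self.k * self.cin
        fan_out = self.k * self.k * self.cout
        self.params["W"] = xavier_uniform(
            (self.k, self.k, self.cin, self.cout), fan_in, fan_out, rng)
        self.params["b"] = np.zeros(self.cout, dtype=DTYPE)

    def out_size(self, in_size: int) -> int:
        return (in_size - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, h, w, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        oh, ow = self.out_size(h), self.out_size(w)
        p, s = self.pad, self.stride
        W, b = self.params["W"], self.params["b"]
        op = np.zeros((n, oh + 2 * p, ow + 2 * p, self.cout), dtype=DTYPE)
        xflat = x.reshape(-1, self.cin)
        for di in range(self.k):
            for dj in range(self.k):
                contrib = (xflat @ W[di, dj]).reshape(n, h, w, self.cout)
                op[:, di:di + s * h:s, dj:dj + s * w:s, :] += contrib
        out = op[:, p:p + oh, p:p + ow, :] + b
        self._cache = (x, (oh, ow))
        return out

    def backward(self, dout):
        x, (oh, ow) = self._cache
        n, h, w, _ = x.shape
        p, s = self.pad, self.stride
        W = self.params["W"]
        dop = np.pad(np.ascontiguousarray(dout, dtype=DTYPE),
                     ((0, 0), (p, p), (p, p), (0, 0)))
        xflat = x.reshape(-1, self.cin)
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        dxflat = dx.reshape(-1, self.cin)
        for di in range(self.k):
            for dj in range(self.k):
                patch = dop[:, di:di + s * h:s, dj:dj + s * w:s, :]
                pf = patch.reshape(-1, self.cout)
                dW[di, dj] = xflat.T @ pf
                dxflat += pf @ W[di, dj].T
        self.grads["W"] = dW
        self.grads["b"] = dout.reshape(-1, self.cout).sum(axis=0)
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2 (valid); spatial dims must be even."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        windows = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
        idx = windows.argmax(axis=3)
        out = np.take_along_axis(windows, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (n, h, w, c) = self._cache
        dwin = np.zeros((n, h // 2, w // 2, 4, c), dtype=DTYPE)
        np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = (dwin.reshape(n, h // 2, w // 2, 2, 2, c)
              .transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c))
        return dx


class Dense(Layer):
    """Fully connected layer with bias."""

    def __init__(self, in_features, out_features, seed=0):
        super().__init__()
        self.fin, self.fout = int(in_features), int(out_features)
        rng = np.random.default_rng(seed)
        self.params["W"] = xavier_uniform((self.fin, self.fout),
                                          self.fin, self.fout, rng)
        self.params["b"] = np.zeros(self.fout, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.shape[-1] != self.fin:
            raise ValueError(f"expected {self.fin} features, got {x.shape[-1]}")
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._cache
        dout = np.ascontiguousarray(dout, dtype=DTYPE)
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    """Reshape trailing dimensions (batch preserved)."""

    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only in training mode; p is the drop rate."""

    def __init__(self, p):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = float(p)

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes (NHWC or NF)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.c = int(channels)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.params["gamma"] = np.ones(self.c, dtype=DTYPE)
        self.params["beta"] = np.zeros(self.c, dtype=DTYPE)
        self.running_mean = np.zeros(self.c, dtype=DTYPE)
        self.running_var = np.ones(self.c, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, axes, shape, train = self._cache
        if not train:  # running stats are constants in eval mode
            self.grads["gamma"] = (dout * xhat).sum(axis=axes)
            self.grads["beta"] = dout.sum(axis=axes)
            return (dout * self.params["gamma"] * inv).astype(DTYPE)
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = dout * self.params["gamma"]
        dx = inv * (g - g.mean(axis=axes)
                    - xhat * (g * xhat).mean(axis=axes))
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        super().__init__()
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.alpha = float(alpha)

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        out = np.empty_like(x, dtype=DTYPE)
        np.negative(np.abs(x), out=out)
        np.exp(out, out=out)
        out = np.where(x >= 0, 1.0 / (1.0 + out), out / (1.0 + out))
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class LSTM(Layer):
    """Single-layer LSTM over (N, T, F) sequences returning the final hidden state.

    Gate order in the stacked weight matrices is (input, forget, cell, output).
    Parameters: W (F x 4H) on the inputs, U (H x 4H) on the recurrent state,
    b (4H), giving 4*((F + H + 1) * H) parameters.  Full BPTT backward.
    """

    def __init__(self, in_features, hidden, seed=0):
        super().__init__()
        self.fin, self.h = int(in_features), int(hidden)
        rng = np.random.default_rng(seed)
        self.params["W"] = xavier_uniform((self.fin, 4 * self.h),
                                          self.fin, 4 * self.h, rng)
        self.params["U"] = xavier_uniform((self.h, 4 * self.h),
                                          self.h, 4 * self.h, rng)
        self.params["b"] = np.zeros(4 * self.h, dtype=DTYPE)

    @staticmethod
    def _sigmoid(x):
        return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, t, f = x.shape
        if f != self.fin:
            raise ValueError(f"expected {self.fin} features per timestep, got {f}")
        H = self.h
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, H), dtype=DTYPE)
        c = np.zeros((n, H), dtype=DTYPE)
        caches = []
        for step in range(t):
            z = x[:, step, :] @ W + h @ U + b
            i = self._sigmoid(z[:, :H])
            fgate = self._sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = self._sigmoid(z[:, 3 * H:])
            c_prev = c
            c = fgate * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            caches.append((x[:, step, :], h_prev, c_prev, i, fgate, g, o, tanh_c))
        self._cache = (caches, x.shape)
        return h

    def backward(self, dout):
        caches, (n, t, f) = self._cache
        H = self.h
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros((n, t, f), dtype=DTYPE)
        dh = np.ascontiguousarray(dout, dtype=DTYPE)
        dc = np.zeros((n, H), dtype=DTYPE)
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, fgate, g, o, tanh_c = caches[step]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * fgate * (1 - fgate),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dW += xt.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ W.T
            dh = dz @ U.T
            dc = dc * fgate
        self.grads["W"], self.grads["U"], self.grads["b"] = dW, dU, db
        return dx


class Sequential:
    """Ordered layer stack with uniform forward/backward and parameter access."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_parameters(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"layer{li}.{type(layer).__name__}.{name}", p

    def parameter_count(self) -> int:
        return sum(layer.parameter_count() for layer in self.layers)

    def get_state(self) -> dict[str, np.ndarray]:
        state = {name: p.copy() for name, p in self.named_parameters()}
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"layer{li}.BatchNorm.running_mean"] = layer.running_mean.copy()
                state[f"layer{li}.BatchNorm.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{li}.{type(layer).__name__}.{name}"
                layer.params[name] = np.asarray(state[key], dtype=DTYPE).copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(
                    state[f"layer{li}.BatchNorm.running_mean"], dtype=DTYPE).copy()
                layer.running_var = np.asarray(
                    state[f"layer{li}.BatchNorm.running_var"], dtype=DTYPE).copy()


# ---------------------------------------------------------------------------
# optimizers


class AdamOptimizer:
    """Adam with bias correction; update is -lr * m_hat / sqrt(v_hat + eps).

    The epsilon sits inside the square root, matching the update rule the
    models here were specified with; with the default eps=1e-8 the
    difference from the more common formulation is negligible.
    """

    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, dict[str, np.ndarray]] = {}
        self.v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, model: Sequential) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # bias correction folded into scalars; updates done in place to keep
        # the 16.8M-parameter W-Net step memory-bound on two passes, not six
        c1 = 1.0 / (1.0 - b1 ** self.t)
        c2 = 1.0 / (1.0 - b2 ** self.t)
        for li, layer in enumerate(model.layers):
            if not layer.params:
                continue
            m = self.m.setdefault(li, {k: np.zeros_like(p)
                                       for k, p in layer.params.items()})
            v = self.v.setdefault(li, {k: np.zeros_like(p)
                                       for k, p in layer.params.items()})
            for k, p in layer.params.items():
                g = layer.grads[k].astype(p.dtype, copy=False)
                m[k] *= b1
                m[k] += (1 - b1) * g
                v[k] *= b2
                np.multiply(g, g, out=g)  # grads are consumed by the step
                v[k] += (1 - b2) * g
                denom = v[k] * np.float32(c2)
                denom += np.float32(self.eps)
                np.sqrt(denom, out=denom)
                np.divide(m[k], denom, out=denom)
                denom *= np.float32(self.lr * c1)
                p -= denom


class MomentumOptimizer:
    """Classic SGD with momentum: v <- gamma*v + lr*g; theta <- theta - v."""

    def __init__(self, lr=1e-5, gamma=0.9):
        self.lr, self.gamma = lr, gamma
        self.v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, model: Sequential) -> None:
        for li, layer in enumerate(model.layers):
            if not layer.params:
                continue
            v = self.v.setdefault(li, {k: np.zeros_like(p)
                                       for k, p in layer.params.items()})
            for k, p in layer.params.items():
                v[k] = self.gamma * v[k] + self.lr * layer.grads[k]
                p -= v[k].astype(p.dtype)
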