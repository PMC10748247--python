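"""A small NumPy neural-network engine for sequence classification.

Implements exactly the layers the window classifier needs — 1-D
convolution ("same" padding), inverted dropout, ReLU, max pooling, a
single-layer LSTM returning its final hidden state, dense layers — with
hand-written forward and backward passes, softmax cross-entropy, and Adam.
All randomness (initialisation, dropout masks, shuffling) flows through a
single :class:`numpy.random.Generator`, so training is bit-reproducible on
one thread. Gradients are exact (the test suite checks every layer against
central finite differences).

Shapes follow the time-series convention ``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> Array:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts by name."""

    def __init__(self) -> None:
        self.params: dict[str, Array] = {}
        self.grads: dict[str, Array] = {}

    def forward(self, x: Array, *, train: bool = False,
                rng: np.random.Generator | None = None) -> Array:
        raise NotImplementedError

    def backward(self, dout: Array) -> Array:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution over time with "same" zero padding.

    Weights ``W`` have shape ``(kernel, in_ch, out_ch)``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        self.params["W"] = _glorot(
            rng, (kernel, in_ch, out_ch), kernel * in_ch, kernel * out_ch
        )
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x, *, train=False, rng=None):
        b, t, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # (B, T, C, k) sliding windows over the padded time axis
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=1
        )
        self._win = win
        self._t = t
        return np.einsum("btck,kcf->btf", win, self.params["W"]) \
            + self.params["b"]

    def backward(self, dout):
        w = self.params["W"]
        self.grads["W"] = np.einsum("btck,btf->kcf", self._win, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        b, t, _ = dout.shape
        dxp = np.zeros(
            (b, t + self.kernel - 1, w.shape[1]), dtype=dout.dtype
        )
        for dk in range(self.kernel):
            dxp[:, dk:dk + t, :] += dout @ w[dk].T
        return dxp[:, self.pad_left:self.pad_left + t, :]


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling over time; a trailing remainder shorter
    than ``pool`` is dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, *, train=False, rng=None):
        b, t, c = x.shape
        t2 = t // self.pool
        xr = x[:, :t2 * self.pool].reshape(b, t2, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout):
        b, t2, c = dout.shape
        dxr = np.zeros((b, t2, self.pool, c), dtype=dout.dtype)
        np.put_along_axis(
            dxr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2
        )
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :t2 * self.pool] = dxr.reshape(b, t2 * self.pool, c)
        return dx


def _sigmoid(z: Array) -> Array:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1 / (1 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1 + ez)
    return out


class LSTM(Layer):
    """Single-layer LSTM emitting only its final hidden state ``(B, H)``.

    Gate layout along the last weight axis is ``[input, forget, cell,
    output]``; the forget-gate bias is initialised to 1 (standard practice
    to ease early gradient flow).
    """

    def __init__(self, in_dim: int, units: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        h = units
        self.params["Wx"] = _glorot(rng, (in_dim, 4 * h), in_dim, 4 * h)
        self.params["Wh"] = _glorot(rng, (h, 4 * h), h, 4 * h)
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0
        self.params["b"] = b

    def forward(self, x, *, train=False, rng=None):
        bsz, t, _ = x.shape
        h = self.units
        wx, wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        ht = np.zeros((bsz, h))
        ct = np.zeros((bsz, h))
        self._cache = []
        self._x = x
        for step in range(t):
            xt = x[:, step, :]
            z = xt @ wx + ht @ wh + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_prev = ct
            ct = f * c_prev + i * g
            tc = np.tanh(ct)
            h_prev = ht
            ht = o * tc
            self._cache.append((xt, h_prev, c_prev, i, f, g, o, ct, tc))
        return ht

    def backward(self, dout):
        x = self._x
        bsz, t, d = x.shape
        h = self.units
        wx, wh = self.params["Wx"], self.params["Wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros(4 * h)
        dx = np.zeros_like(x)
        dh = dout
        dc = np.zeros((bsz, h))
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, ct, tc = self._cache[step]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ], axis=1)
            dwx += xt.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ wx.T
            dh = dz @ wh.T
            dc = dc * f
        self.grads["Wx"] = dwx
        self.grads["Wh"] = dwh
        self.grads["b"] = db
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: Array, *, train: bool = False,
                rng: np.random.Generator | None = None) -> Array:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: Array) -> Array:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self.layers for name in l.params]

    def n_parameters(self) -> int:
        return sum(l.params[n].size for l, n in self.parameters())

    def state_arrays(self) -> dict[str, Array]:
        """Flat name->array view of all weights, for persistence."""
        return {
            f"layer{i:02d}_{name}": layer.params[name]
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state(self, arrays: dict[str, Array]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{i:02d}_{name}"
                src = arrays[key]
                if src.shape != layer.params[name].shape:
                    raise ValueError(f"shape mismatch for {key}")
                layer.params[name] = src.astype(float).copy()


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: Array, onehot: Array,
) -> tuple[float, Array]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n)
    return loss, (p - onehot) / n


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {
            id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
            for l in model.layers
        }
        self.v = {
            id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
            for l in model.layers
        }

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m[id(layer)][name]
            v = self.v[id(layer)][name]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
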