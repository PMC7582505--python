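"""Minimal NumPy neural-network engine for the score regressors.

Implements exactly the layers the CNN and ResNet configurations need —
2-D convolution, 2×2 max pooling, batch normalisation, dense, ELU,
dropout, global average pooling and residual blocks — together with an
Adam optimiser and a mean-squared-error training loop.  Everything is
float32, single-threaded and deterministic given a seed.

Layout convention is channels-last: 4-D activations are
``(batch, height, width, channels)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "MaxPool2D", "Dense", "ELU", "Dropout", "Flatten",
    "BatchNorm", "GlobalAveragePool", "ResidualBlock", "Network", "Adam",
    "fit_mse",
]

_F32 = np.float32


def _pair(v):
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class Layer:
    """Base layer: ``build`` fixes shapes and allocates parameters."""

    def build(self, in_shape, rng: np.random.Generator):
        return in_shape

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g, need_input_grad=True):  # pragma: no cover
        raise NotImplementedError

    def param_pairs(self):
        """(parameter, gradient) array pairs; both mutated in place."""
        return []

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.param_pairs())


class Conv2D(Layer):
    """2-D convolution (cross-correlation), stride and Keras-style padding."""

    def __init__(self, filters, kernel_size, stride=1, padding="valid"):
        self.filters = int(filters)
        self.kh, self.kw = _pair(kernel_size)
        self.sh, self.sw = _pair(stride)
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding

    def build(self, in_shape, rng):
        h, w, c = in_shape
        if self.padding == "same":
            ph = max((int(np.ceil(h / self.sh)) - 1) * self.sh + self.kh - h, 0)
            pw = max((int(np.ceil(w / self.sw)) - 1) * self.sw + self.kw - w, 0)
            self._pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        else:
            self._pads = (0, 0, 0, 0)
        hp = h + self._pads[0] + self._pads[1]
        wp = w + self._pads[2] + self._pads[3]
        if hp < self.kh or wp < self.kw:
            raise ValueError(
                f"kernel {(self.kh, self.kw)} larger than input {(h, w)}")
        self.in_channels = c
        oh = (hp - self.kh) // self.sh + 1
        ow = (wp - self.kw) // self.sw + 1
        fan_in = self.kh * self.kw * c
        fan_out = self.kh * self.kw * self.filters
        self.W = glorot_uniform(rng, (self.kh, self.kw, c, self.filters),
                                fan_in, fan_out)
        self.b = np.zeros(self.filters, dtype=_F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        return (oh, ow, self.filters)

    def param_pairs(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, training=False):
        pt, pb, pl, pr = self._pads
        if any(self._pads):
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        n = x.shape[0]
        v = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        v = v[:, ::self.sh, ::self.sw]          # (n, oh, ow, c, kh, kw)
        oh, ow = v.shape[1], v.shape[2]
        cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n * oh * ow, self.kh * self.kw * self.in_channels)
        self._cols = cols
        self._padded_shape = x.shape
        out = cols @ self.W.reshape(-1, self.filters) + self.b
        return out.reshape(n, oh, ow, self.filters)

    def backward(self, g, need_input_grad=True):
        n, oh, ow, f = g.shape
        gmat = g.reshape(-1, f).astype(_F32, copy=False)
        self.gW[...] = (self._cols.T @ gmat).reshape(self.W.shape)
        self.gb[...] = gmat.sum(axis=0)
        self._cols = None
        if not need_input_grad:
            return None
        _, hp, wp, c = self._padded_shape
        if self.sh > 1 or self.sw > 1:
            gd = np.zeros((n, (oh - 1) * self.sh + 1, (ow - 1) * self.sw + 1, f),
                          dtype=_F32)
            gd[:, ::self.sh, ::self.sw] = g
        else:
            gd = g
        # full correlation with the spatially flipped kernel
        gp = np.pad(gd, ((0, 0),
                         (self.kh - 1, hp - gd.shape[1]),
                         (self.kw - 1, wp - gd.shape[2]),
                         (0, 0)))
        v = sliding_window_view(gp, (self.kh, self.kw), axis=(1, 2))
        cols2 = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        cols2 = cols2.reshape(n * hp * wp, self.kh * self.kw * f)
        wb = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        gx = (cols2 @ wb.reshape(-1, c)).reshape(n, hp, wp, c)
        pt, pb, pl, pr = self._pads
        if any(self._pads):
            gx = gx[:, pt:hp - pb, pl:wp - pr, :]
        return gx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols are dropped."""

    def __init__(self, pool_size=(2, 2)):
        self.ph, self.pw = _pair(pool_size)

    def build(self, in_shape, rng):
        h, w, c = in_shape
        if h < self.ph or w < self.pw:
            raise ValueError("pooling window larger than input")
        return (h // self.ph, w // self.pw, c)

    def _cells(self, x):
        n, h, w, c = x.shape
        oh, ow = h // self.ph, w // self.pw
        return [(di, dj, x[:, di:oh * self.ph:self.ph,
                           dj:ow * self.pw:self.pw, :])
                for di in range(self.ph) for dj in range(self.pw)]

    def forward(self, x, training=False):
        m = None
        for _, _, v in self._cells(x):
            m = v.copy() if m is None else np.maximum(m, v, out=m)
        self._x = x
        self._max = m
        return m

    def backward(self, g, need_input_grad=True):
        if not need_input_grad:
            self._x = None
            return None
        n, h, w, c = self._x.shape
        oh, ow = h // self.ph, w // self.pw
        gx = np.zeros(self._x.shape, dtype=_F32)
        claimed = np.zeros(self._max.shape, dtype=bool)
        # route each gradient to the first cell attaining the maximum
        for di, dj, v in self._cells(self._x):
            hit = (v == self._max) & ~claimed
            gx[:, di:oh * self.ph:self.ph, dj:ow * self.pw:self.pw, :] = \
                np.where(hit, g, 0.0)
            claimed |= hit
        self._x = None
        return gx


class Flatten(Layer):
    def build(self, in_shape, rng):
        self._in_shape = tuple(in_shape)
        return (int(np.prod(in_shape)),)

    def forward(self, x, training=False):
        return x.reshape(x.shape[0], -1)

    def backward(self, g, need_input_grad=True):
        if not need_input_grad:
            return None
        return g.reshape((g.shape[0],) + self._in_shape)


class Dense(Layer):
    def __init__(self, units):
        self.units = int(units)

    def build(self, in_shape, rng):
        (d,) = in_shape
        self.W = glorot_uniform(rng, (d, self.units), d, self.units)
        self.b = np.zeros(self.units, dtype=_F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        return (self.units,)

    def param_pairs(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g, need_input_grad=True):
        g = g.astype(_F32, copy=False)
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        self._x = None
        if not need_input_grad:
            return None
        return g @ self.W.T


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = float(alpha)

    def forward(self, x, training=False):
        y = np.where(x > 0, x,
                     self.alpha * np.expm1(np.minimum(x, 0.0))).astype(_F32)
        if training:
            self._deriv = np.where(x > 0, _F32(1.0),
                                   y + _F32(self.alpha))
        return y

    def backward(self, g, need_input_grad=True):
        if not need_input_grad:
            self._deriv = None
            return None
        g = g * self._deriv
        self._deriv = None
        return g


class Dropout(Layer):
    """Inverted dropout; the mask RNG is seeded at build time."""

    def __init__(self, rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("dropout rate must lie in [0, 1]")
        self.rate = float(rate)

    def build(self, in_shape, rng):
        self._rng = np.random.default_rng(rng.integers(2 ** 31))
        return in_shape

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rate >= 1.0:
            self._mask = np.zeros_like(x)
            return self._mask
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, g, need_input_grad=True):
        if not need_input_grad:
            return None
        if self._mask is None:
            return g
        return g * self._mask


class BatchNorm(Layer):
    """Batch normalisation over all axes but the last (channel) axis."""

    def __init__(self, momentum=0.9, eps=1e-5):
        self.momentum = float(momentum)
        self.eps = float(eps)

    def build(self, in_shape, rng):
        c = in_shape[-1]
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        return in_shape

    def param_pairs(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
            self._m = x.size // x.shape[-1]
            self._std = np.sqrt(var + self.eps).astype(_F32)
            self._xhat = ((x - mean) / self._std).astype(_F32)
            return self.gamma * self._xhat + self.beta
        std = np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) / std + self.beta

    def backward(self, g, need_input_grad=True):
        axes = tuple(range(g.ndim - 1))
        self.ggamma[...] = (g * self._xhat).sum(axis=axes)
        self.gbeta[...] = g.sum(axis=axes)
        if not need_input_grad:
            self._xhat = None
            return None
        m = self._m
        dxhat = g * self.gamma
        gx = (dxhat - dxhat.mean(axis=axes)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes))
        gx = (gx / self._std).astype(_F32)
        self._xhat = None
        return gx


class GlobalAveragePool(Layer):
    def build(self, in_shape, rng):
        h, w, c = in_shape
        self._hw = h * w
        self._in_shape = tuple(in_shape)
        return (c,)

    def forward(self, x, training=False):
        return x.mean(axis=(1, 2))

    def backward(self, g, need_input_grad=True):
        if not need_input_grad:
            return None
        n, c = g.shape
        h, w, _ = self._in_shape
        return np.broadcast_to(g[:, None, None, :] / self._hw,
                               (n, h, w, c)).astype(_F32)


class ResidualBlock(Layer):
    """Post-activation residual block: conv-BN-ELU-conv-BN (+shortcut), ELU.

    The first convolution is 3×3; the second kernel is configurable.  A
    1×1 strided projection shortcut is inserted whenever the block changes
    resolution or channel count, otherwise the shortcut is the identity.
    """

    def __init__(self, filters, second_kernel=(3, 3), stride=1):
        self.filters = int(filters)
        self.second_kernel = _pair(second_kernel)
        self.stride = int(stride)
        self.main = [
            Conv2D(self.filters, (3, 3), stride=self.stride, padding="same"),
            BatchNorm(), ELU(),
            Conv2D(self.filters, self.second_kernel, padding="same"),
            BatchNorm(),
        ]
        self.shortcut: list[Layer] = []
        self.out_act = ELU()

    def build(self, in_shape, rng):
        shape = in_shape
        for layer in self.main:
            shape = layer.build(shape, rng)
        if self.stride != 1 or in_shape[-1] != self.filters:
            self.shortcut = [
                Conv2D(self.filters, (1, 1), stride=self.stride,
                       padding="same"),
                BatchNorm(),
            ]
            s_shape = in_shape
            for layer in self.shortcut:
                s_shape = layer.build(s_shape, rng)
            if tuple(s_shape) != tuple(shape):
                raise ValueError("shortcut/main shape mismatch in block")
        self.out_act.build(shape, rng)
        return shape

    def param_pairs(self):
        pairs = []
        for layer in self.main + self.shortcut:
            pairs.extend(layer.param_pairs())
        return pairs

    def forward(self, x, training=False):
        h = x
        for layer in self.main:
            h = layer.forward(h, training)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, training)
        return self.out_act.forward(h + s, training)

    def backward(self, g, need_input_grad=True):
        g = self.out_act.backward(g)
        gm = g
        for layer in reversed(self.main):
            gm = layer.backward(gm, need_input_grad=True)
        gs = g
        for layer in reversed(self.shortcut):
            gs = layer.backward(gs, need_input_grad=True)
        if not need_input_grad:
            return None
        return gm + gs


class Network:
    """A built, seeded layer stack mapping input tensors to one score."""

    def __init__(self, layers, input_shape, seed):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape
        self._pairs = []
        for layer in self.layers:
            self._pairs.extend(layer.param_pairs())

    def param_pairs(self):
        return self._pairs

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self._pairs)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            g = layer.backward(g, need_input_grad=not last)
        return g

    def get_weights(self):
        return [p.copy() for p, _ in self._pairs]

    def set_weights(self, weights):
        if len(weights) != len(self._pairs):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(self._pairs, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w


class Adam:
    def __init__(self, param_pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.pairs = param_pairs
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in param_pairs]
        self.v = [np.zeros_like(p) for p, _ in param_pairs]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_global_norm(param_pairs, max_norm: float):
    total = 0.0
    for _, g in param_pairs:
        total += float(np.sum(g.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = _F32(max_norm / norm)
        for _, g in param_pairs:
            g *= scale
    return norm


def fit_mse(net: Network, x, y, *, epochs, batch_size, lr, seed,
            clip_norm: float = 5.0, collapse_epoch: int | None = None,
            collapse_threshold: float | None = None):
    """Minibatch MSE training with Adam; returns the per-epoch loss trace.

    Gradients are clipped to a global L2 norm of ``clip_norm`` before each
    Adam step: spectral-power features are heavy-tailed and an occasional
    extreme minibatch can otherwise throw the ELU stack into the saturated
    (constant-output) regime it cannot leave.

    If ``collapse_epoch``/``collapse_threshold`` are set, training stops
    early (returning the partial trace) when the loss after that many epochs
    is still above the threshold — the caller can then restart from a fresh
    initialisation.
    """
    x = np.asarray(x, dtype=_F32)
    y = np.asarray(y, dtype=_F32).ravel()
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    pairs = net.param_pairs()
    opt = Adam(pairs, lr=lr)
    losses = []
    n = len(x)
    for _ in range(int(epochs)):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = net.forward(x[idx], training=True)[:, 0]
            diff = pred - y[idx]
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            g = (2.0 * diff / len(idx)).astype(_F32)[:, None]
            net.backward(g)
            if clip_norm is not None:
                clip_global_norm(pairs, clip_norm)
            opt.step()
            total += loss * len(idx)
        losses.append(total / n)
        if (collapse_epoch is not None
                and len(losses) == collapse_epoch
                and losses[-1] > collapse_threshold):
            break
    return np.asarray(losses)
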