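"""Layers and the four regression architectures.

All models map one pre-impact window (50 time steps x 8 channels) to a single
predicted peak acceleration in g.  Convolutions use kernel 2 / stride 2 (1-D)
or kernel (4,4) / stride (2,2) with same-padding (2-D), each followed by ReLU
and max-pooling of 2 or (2,2); recurrent layers are standard LSTMs; a dropout
of 0.25 precedes the single linear output unit.  Batch size is 1 everywhere,
so layers operate on unbatched samples.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, max_along, pad

__all__ = ["Dense", "Conv1D", "Conv2DSame", "LSTMLayer", "maxpool1d",
           "maxpool2d", "dropout", "build_network", "Network"]


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class Conv1D:
    """1-D convolution, kernel 2, stride 2, valid padding.

    With this geometry each output step sees a disjoint sample pair, so the
    convolution is a reshape followed by one matmul.
    """

    KERNEL = 2
    STRIDE = 2

    def __init__(self, rng, in_ch: int, filters: int):
        fan_in = self.KERNEL * in_ch
        self.W = Tensor(_glorot(rng, (fan_in, filters), fan_in, filters), requires_grad=True)
        self.b = Tensor(np.zeros((1, filters)), requires_grad=True)
        self.in_ch = in_ch

    def __call__(self, x: Tensor) -> Tensor:     # x: (T, C) -> (T//2, F)
        t_out = x.shape[0] // 2
        xc = x[: 2 * t_out].reshape(t_out, 2 * self.in_ch)
        return xc @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class Conv2DSame:
    """2-D convolution, kernel (4,4), stride (2,2), same-padding."""

    K = 4
    S = 2

    def __init__(self, rng, in_ch: int, filters: int):
        fan_in = self.K * self.K * in_ch
        self.W = Tensor(_glorot(rng, (self.K, self.K, in_ch, filters), fan_in, filters),
                        requires_grad=True)
        self.b = Tensor(np.zeros((1, filters)), requires_grad=True)
        self.in_ch = in_ch
        self.filters = filters

    def __call__(self, x: Tensor) -> Tensor:     # x: (H, W, C) -> (ceil(H/2), ceil(W/2), F)
        h, w, _ = x.shape
        ho = -(-h // self.S)
        wo = -(-w // self.S)
        pad_h = max((ho - 1) * self.S + self.K - h, 0)
        pad_w = max((wo - 1) * self.S + self.K - w, 0)
        xp = pad(x, ((pad_h // 2, pad_h - pad_h // 2),
                     (pad_w // 2, pad_w - pad_w // 2), (0, 0)))
        acc = None
        for di in range(self.K):
            for dj in range(self.K):
                sl = xp[di: di + self.S * (ho - 1) + 1: self.S,
                        dj: dj + self.S * (wo - 1) + 1: self.S, :]
                term = sl.reshape(ho * wo, self.in_ch) @ self.W[di, dj]
                acc = term if acc is None else acc + term
        return (acc + self.b).reshape(ho, wo, self.filters)

    def params(self):
        return [self.W, self.b]


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:   # (T, F) -> (T//size, F)
    t_out = x.shape[0] // size
    return max_along(x[: size * t_out].reshape(t_out, size, x.shape[1]), axis=1)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """(H, W, F) max-pool with the window clipped to the available extent.

    Axes shorter than the pool size are left untouched, so a width-1 feature
    map pools only along the time axis.
    """
    h, w, f = x.shape
    if h >= size:
        ho = h // size
        x = max_along(x[: size * ho].reshape(ho, size, w, f), axis=1)
        h = ho
    if w >= size:
        wo = w // size
        x = max_along(x[:, : size * wo].reshape(h, wo, size, f), axis=2)
    return x


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference)."""
    if rng is None or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q if rows >= cols else q.T


class LSTMLayer:
    """Standard LSTM: sigmoid gates, tanh candidate/output, forget bias 1,
    Glorot input weights and orthogonal recurrent weights (per-gate blocks)."""

    def __init__(self, rng, n_in: int, units: int):
        self.units = units
        self.Wx = Tensor(_glorot(rng, (n_in, 4 * units), n_in, units), requires_grad=True)
        wh = np.concatenate([_orthogonal(rng, units, units) for _ in range(4)], axis=1)
        self.Wh = Tensor(wh, requires_grad=True)
        b = np.zeros((1, 4 * units))
        b[0, units: 2 * units] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, return_sequences: bool) -> Tensor:
        u = self.units
        h = Tensor(np.zeros((1, u)))
        c = Tensor(np.zeros((1, u)))
        outputs = []
        for t in range(x.shape[0]):
            xt = x[t: t + 1]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = z[:, :u].sigmoid()
            f = z[:, u: 2 * u].sigmoid()
            g = z[:, 2 * u: 3 * u].tanh()
            o = z[:, 3 * u:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            if return_sequences:
                outputs.append(h)
        return concat(outputs, axis=0) if return_sequences else h

    def params(self):
        return [self.Wx, self.Wh, self.b]


class Network:
    """Base: a list of layers plus a seeded forward pass."""

    dropout_p = 0.25

    def __init__(self):
        self._layers = []

    def params(self):
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def get_state(self):
        return [p.data.copy() for p in self.params()]

    def set_state(self, state):
        for p, arr in zip(self.params(), state):
            p.data = arr.copy()

    def forward(self, x: np.ndarray, drop_rng=None) -> Tensor:
        raise NotImplementedError


class CNN1DNet(Network):
    """Two conv(k2,s2)+pool(2) blocks: 50 -> 25 -> 12 -> 6 -> 3 steps."""

    input_shape = (50, 8)

    def __init__(self, rng, f1: int, f2: int):
        super().__init__()
        self.c1 = Conv1D(rng, 8, f1)
        self.c2 = Conv1D(rng, f1, f2)
        self.head = Dense(rng, 3 * f2, 1)
        self._layers = [self.c1, self.c2, self.head]

    def forward(self, x, drop_rng=None):
        h = maxpool1d(self.c1(Tensor(x)).relu())
        h = maxpool1d(self.c2(h).relu())
        h = dropout(h.reshape(1, -1), self.dropout_p, drop_rng)
        return self.head(h).reshape(())


class CNN2DNet(Network):
    """Two conv((4,4),(2,2),same)+pool((2,2)) blocks: 50x8 -> 25x4 -> 12x2 -> 6x1 -> 3x1."""

    input_shape = (50, 8, 1)

    def __init__(self, rng, f1: int, f2: int):
        super().__init__()
        self.c1 = Conv2DSame(rng, 1, f1)
        self.c2 = Conv2DSame(rng, f1, f2)
        self.head = Dense(rng, 3 * f2, 1)
        self._layers = [self.c1, self.c2, self.head]

    def forward(self, x, drop_rng=None):
        h = maxpool2d(self.c1(Tensor(x)).relu())
        h = maxpool2d(self.c2(h).relu())
        h = dropout(h.reshape(1, -1), self.dropout_p, drop_rng)
        return self.head(h).reshape(())


class LSTMNet(Network):
    """Two stacked LSTMs over the raw 50-step sequence."""

    input_shape = (50, 8)

    def __init__(self, rng, u1: int, u2: int):
        super().__init__()
        self.l1 = LSTMLayer(rng, 8, u1)
        self.l2 = LSTMLayer(rng, u1, u2)
        self.head = Dense(rng, u2, 1)
        self._layers = [self.l1, self.l2, self.head]

    def forward(self, x, drop_rng=None):
        h = self.l1(Tensor(x), return_sequences=True)
        h = self.l2(h, return_sequences=False)
        h = dropout(h, self.dropout_p, drop_rng)
        return self.head(h).reshape(())


class ConvLSTMNet(Network):
    """Two conv(k2,s2)+pool blocks feeding two LSTMs (3 remaining steps)."""

    input_shape = (50, 8)

    def __init__(self, rng, f1: int, f2: int, u3: int, u4: int):
        super().__init__()
        self.c1 = Conv1D(rng, 8, f1)
        self.c2 = Conv1D(rng, f1, f2)
        self.l1 = LSTMLayer(rng, f2, u3)
        self.l2 = LSTMLayer(rng, u3, u4)
        self.head = Dense(rng, u4, 1)
        self._layers = [self.c1, self.c2, self.l1, self.l2, self.head]

    def forward(self, x, drop_rng=None):
        h = maxpool1d(self.c1(Tensor(x)).relu())
        h = maxpool1d(self.c2(h).relu())
        h = self.l1(h, return_sequences=True)
        h = self.l2(h, return_sequences=False)
        h = dropout(h, self.dropout_p, drop_rng)
        return self.head(h).reshape(())


_BUILDERS = {"cnn1d": CNN1DNet, "cnn2d": CNN2DNet, "lstm": LSTMNet,
             "convlstm": ConvLSTMNet}


def build_network(architecture: str, layer_sizes, rng: np.random.Generator) -> Network:
    return _BUILDERS[architecture](rng, *layer_sizes)
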