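"""A small NumPy neural-network engine for epoch classification.

Implements exactly the layer types the classifier needs — stride-1 "same"
2-D convolution, inverted dropout, 2x2 valid max-pooling, flatten and dense
layers with ReLU — together with a softmax cross-entropy head and the Adam
optimizer.  Convolutions run as im2col GEMMs in float32; all randomness
(initialization, shuffling, dropout) flows from explicit generators so
training is deterministic for a given seed.

Gradients are exact (verified by finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "Dropout", "MaxPool2D", "Flatten", "Dense",
           "Network", "Adam", "softmax", "relu"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot_uniform(shape, fan_in, fan_out, rng):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _correlate2d(x, w, pad_top, pad_left):
    """Stride-1 valid cross-correlation of padded ``x`` with kernel ``w``.

    x : (N, H, W, C); w : (kh, kw, C, F); pads give the left/top margin, the
    right/bottom margin is ``k - 1 - pad`` so output spatial dims equal input.
    Returns (y, cols) where cols is the (N*H*W, kh*kw*C) im2col matrix.
    """
    kh, kw, cin, f = w.shape
    xp = np.pad(x, ((0, 0), (pad_top, kh - 1 - pad_top),
                    (pad_left, kw - 1 - pad_left), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    n, h, wd = win.shape[:3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)
                                ).reshape(n * h * wd, kh * kw * cin)
    y = (cols @ w.reshape(kh * kw * cin, f)).reshape(n, h, wd, f)
    return y, cols


class Conv2D:
    """Stride-1 'same' convolution with optional ReLU.

    'Same' padding puts ``(k-1)//2`` zeros before and the remainder after,
    so even kernels pad one more at the bottom/right (Keras convention).
    """

    def __init__(self, in_channels, filters, kernel, activation="relu", rng=None):
        self.kh, self.kw = kernel
        self.in_channels, self.filters = in_channels, filters
        self.activation = activation
        rng = rng or np.random.default_rng()
        fan_in = self.kh * self.kw * in_channels
        fan_out = self.kh * self.kw * filters
        self.W = glorot_uniform((self.kh, self.kw, in_channels, filters),
                                fan_in, fan_out, rng)
        self.b = np.zeros(filters, dtype=np.float32)
        self.pad_top, self.pad_left = (self.kh - 1) // 2, (self.kw - 1) // 2

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, training=False, rng=None):
        y, self._cols = _correlate2d(x, self.W, self.pad_top, self.pad_left)
        y += self.b
        if self.activation == "relu":
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, dy, need_dx=True):
        if self.activation == "relu":
            dy = np.where(self._mask, dy, 0.0)
        n, h, w, f = dy.shape
        dyr = dy.reshape(n * h * w, f)
        self.dW = (self._cols.T @ dyr).reshape(self.W.shape)
        self.db = dyr.sum(axis=0)
        self._cols = None
        if not need_dx:
            return None
        # dx: correlate dy with the spatially flipped, channel-transposed kernel
        wflip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,F,C)
        dx, _ = _correlate2d(dy, np.ascontiguousarray(wflip),
                             self.kh - 1 - self.pad_top,
                             self.kw - 1 - self.pad_left)
        return dx

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dropout:
    """Inverted dropout: active only during training."""

    def __init__(self, rate=0.5):
        self.rate = rate
        self.n_params = 0

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params_and_grads(self):
        return []


class MaxPool2D:
    """2x2, stride-2, valid max pooling; trailing odd rows/cols are dropped.

    Gradient is split equally among tied maxima within a window (ties are
    measure-zero for continuous inputs).
    """

    def __init__(self, pool=(2, 2)):
        self.ph, self.pw = pool
        self.n_params = 0

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // self.ph, w // self.pw
        if h2 < 1 or w2 < 1:
            raise ValueError(f"input {h}x{w} too small for "
                             f"{self.ph}x{self.pw} pooling")
        self._in_shape = x.shape
        xc = x[:, : h2 * self.ph, : w2 * self.pw, :]
        win = xc.reshape(n, h2, self.ph, w2, self.pw, c)
        out = win.max(axis=(2, 4))
        self._win, self._out = win, out
        return out

    def backward(self, dy):
        n, h2, w2, c = dy.shape
        mask = self._win == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dwin = mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : h2 * self.ph, : w2 * self.pw, :] = dwin.reshape(
            n, h2 * self.ph, w2 * self.pw, c)
        self._win = self._out = None
        return dx

    def params_and_grads(self):
        return []


class Flatten:
    def __init__(self):
        self.n_params = 0

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params_and_grads(self):
        return []


class Dense:
    """Fully connected layer; activation 'relu', 'softmax' or None.

    A 'softmax' dense layer outputs logits from :meth:`forward`; the network
    head folds the softmax into the cross-entropy loss, and
    :meth:`Network.predict_proba` applies :func:`softmax` explicitly.
    """

    def __init__(self, in_dim, units, activation=None, rng=None):
        rng = rng or np.random.default_rng()
        self.in_dim, self.units, self.activation = in_dim, units, activation
        self.W = glorot_uniform((in_dim, units), in_dim, units, rng)
        self.b = np.zeros(units, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = np.where(self._mask, dy, 0.0)
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params_and_grads):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g in params_and_grads:
            key = id(p)
            if key not in self._state:
                self._state[key] = (np.zeros_like(p, dtype=np.float64),
                                    np.zeros_like(p, dtype=np.float64))
            m, v = self._state[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                  ).astype(p.dtype)


class Network:
    """A plain feed-forward stack trained with softmax cross-entropy."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x  # logits

    def backward(self, delta, need_input_grad=False):
        """Backpropagate; skips the first layer's input gradient by default
        (it feeds nothing during training)."""
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i]
            if i == 0 and not need_input_grad and isinstance(layer, Conv2D):
                layer.backward(delta, need_dx=False)
                return None
            delta = layer.backward(delta)
        return delta

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    def predict_proba(self, x, batch_size=64):
        x = np.asarray(x, dtype=np.float32)
        chunks = [softmax(self.forward(x[i:i + batch_size], training=False))
                  for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(chunks, axis=0)

    def predict(self, x, batch_size=64):
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def loss_and_delta(self, logits, y_onehot, sample_weight=None):
        """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
        p = softmax(logits)
        n = logits.shape[0]
        logp = np.log(np.clip((p * y_onehot).sum(axis=1), 1e-12, None))
        if sample_weight is None:
            loss = -logp.mean()
            delta = (p - y_onehot) / n
        else:
            loss = -(sample_weight * logp).sum() / n
            delta = sample_weight[:, None] * (p - y_onehot) / n
        return float(loss), delta.astype(np.float32)

    def fit(self, x, y, epochs, batch_size=32, lr=1e-3, seed=0,
            class_weight=None, shuffle=True):
        """Mini-batch Adam training.

        Parameters
        ----------
        x : (N, H, W, 1) float array; y : (N,) integer class labels.
        class_weight : None, 'balanced', or a mapping class -> weight.
            'balanced' uses ``n_samples / (n_classes * count_c)``.

        Returns the per-training-epoch mean loss history (length ``epochs``).
        """
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        n = x.shape[0]
        n_classes = self.layers[-1].units
        y_onehot = np.eye(n_classes, dtype=np.float32)[y]

        weights = None
        if class_weight == "balanced":
            counts = np.bincount(y, minlength=n_classes).astype(float)
            cw = np.where(counts > 0, n / (n_classes * np.maximum(counts, 1)), 0.0)
            weights = cw[y].astype(np.float32)
        elif isinstance(class_weight, dict):
            weights = np.array([class_weight.get(int(c), 1.0) for c in y],
                               dtype=np.float32)

        rng = np.random.default_rng(seed)
        opt = Adam(lr=lr)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            total, seen = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                logits = self.forward(x[idx], training=True, rng=rng)
                loss, delta = self.loss_and_delta(
                    logits, y_onehot[idx],
                    None if weights is None else weights[idx])
                self.backward(delta)
                opt.step(self.params_and_grads())
                total += loss * len(idx)
                seen += len(idx)
            history.append(total / seen)
        return history
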