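"""Minimal numpy layer framework used by the network builder.

Implements exactly the layer set the classifier needs — 2-D convolution
(im2col + BLAS matmul), batch normalization, elementwise activation,
max pooling, flatten, dense — with hand-written backward passes and an
Adam optimizer.  Arrays are channel-last ``(N, H, W, C)`` float32.

Everything is deterministic given the ``numpy.random.Generator`` used
for initialization and the shuffling generator used by the training
loop; there are no hidden sources of randomness.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import ActivationSpec, activate, activate_grad

__all__ = ["Model", "Adam", "softmax", "cross_entropy"]


class Layer:
    """Base layer: ``params``/``grads`` dicts and forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """k×k convolution, zero padding, He fan-in init, bias per filter."""

    def __init__(self, in_channels: int, filters: int, kernel: tuple[int, int],
                 stride: tuple[int, int], padding: int, rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.in_channels = in_channels
        self.filters = filters
        fan_in = kh * kw * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_channels, kh, kw, filters))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(filters, np.float32)}

    def _cols(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        sh, sw = self.stride
        p = self.padding
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._padded_shape = x.shape
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, H', W', C, kh, kw)
        win = win[:, ::sh, ::sw]
        self._out_hw = win.shape[1:3]
        n, ho, wo = win.shape[0], win.shape[1], win.shape[2]
        # window layout (C, kh, kw) matches the weight layout
        return np.ascontiguousarray(win.transpose(0, 1, 2, 3, 4, 5)).reshape(
            n * ho * wo, self.in_channels * kh * kw)

    def forward(self, x, train):
        self._in_shape = x.shape
        cols = self._cols(x)
        self._cols_cache = cols
        kh, kw = self.kernel
        wmat = self.params["w"].reshape(self.in_channels * kh * kw, self.filters)
        out = cols @ wmat + self.params["b"]
        ho, wo = self._out_hw
        return out.reshape(x.shape[0], ho, wo, self.filters)

    def backward(self, dout):
        n, ho, wo, f = dout.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        p = self.padding
        dflat = dout.reshape(n * ho * wo, f)
        wmat = self.params["w"].reshape(-1, f)
        self.grads["w"] = (self._cols_cache.T @ dflat).reshape(self.params["w"].shape)
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ wmat.T).reshape(n, ho, wo, self.in_channels, kh, kw)
        dxp = np.zeros(self._padded_shape, np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + sh * ho:sh, j:j + sw * wo:sw, :] += dcols[:, :, :, :, i, j]
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalization with learnable scale and offset.

    Running statistics (state, not learnables) use momentum 0.1 and the
    biased batch variance; inference normalizes with the running values.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels, np.float32),
                       "beta": np.zeros(channels, np.float32)}
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.frozen = False  # freeze running-stat updates (used in tests)

    def forward(self, x, train):
        self._train_mode = train
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self.frozen:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._n = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        if not self._train_mode:
            return (dout * g * self._istd).astype(np.float32)
        n = self._n
        dxhat = dout * g
        dx = (self._istd / n) * (n * dxhat
                                 - dxhat.sum(axis=axes)
                                 - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        return dx.astype(np.float32)


class Activation(Layer):
    """Elementwise nonlinearity from :mod:`actsign.activations`."""

    def __init__(self, spec: ActivationSpec):
        super().__init__()
        self.spec = spec

    def forward(self, x, train):
        self._x = x
        return activate(self.spec, x).astype(np.float32)

    def backward(self, dout):
        return dout * activate_grad(self.spec, self._x).astype(np.float32)


class MaxPool2D(Layer):
    """Max pooling; padded positions (for 'same'-style pools) hold -inf."""

    def __init__(self, kernel: tuple[int, int], stride: tuple[int, int], padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x, train):
        kh, kw = self.kernel
        sh, sw = self.stride
        p = self.padding
        self._in_shape = x.shape
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)),
                       constant_values=-np.inf)
        self._padded_shape = x.shape
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::sh, ::sw]
        n, ho, wo, c = win.shape[:4]
        flat = win.reshape(n, ho, wo, c, kh * kw)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout):
        kh, kw = self.kernel
        sh, sw = self.stride
        p = self.padding
        n, ho, wo, c = dout.shape
        g = np.zeros((n, ho, wo, c, kh * kw), np.float32)
        np.put_along_axis(g, self._argmax[..., None], dout[..., None], axis=-1)
        dxp = np.zeros(self._padded_shape, np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + sh * ho:sh, j:j + sw * wo:sw, :] += g[..., i * kw + j]
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, He fan-in init."""

    def __init__(self, in_features: int, out_units: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_units))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_units, np.float32)}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmax outputs."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p).mean())


class Model:
    """A sequential stack of layers ending in a linear class-score head.

    ``forward`` returns pre-softmax logits; probabilities come from
    :func:`softmax`.  ``capture=True`` records every layer's output so
    that gradients with respect to an intermediate representation (as
    Grad-CAM needs) can be requested via :meth:`grad_wrt_layer`.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int],
                 num_classes: int):
        self.layers = layers
        self.input_shape = input_shape
        self.num_classes = num_classes

    def forward(self, x: np.ndarray, train: bool = False,
                capture: bool = False) -> np.ndarray:
        x = np.asarray(x, np.float32)
        self._captured = [] if capture else None
        for layer in self.layers:
            x = layer.forward(x, train)
            if capture:
                self._captured.append(x)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def grad_wrt_layer(self, layer_index: int, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate ``dlogits`` down to the output of ``layer_index``.

        Requires the preceding ``forward`` to have been run on the same
        input (layer caches are reused); does not touch layers at or
        below ``layer_index``.
        """
        d = dlogits
        for layer in reversed(self.layers[layer_index + 1:]):
            d = layer.backward(d)
        return d

    def captured_output(self, layer_index: int) -> np.ndarray:
        if self._captured is None:
            raise RuntimeError("run forward(..., capture=True) first")
        return self._captured[layer_index]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def parameter_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def parameters(self):
        """Yield (layer, name, array) triples of trainable parameters."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name, layer.params[name]

    def get_state(self) -> list:
        """Deep-copied parameter + batchnorm-state snapshot."""
        state = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm2D):
                entry["_running_mean"] = layer.running_mean.copy()
                entry["_running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = entry["_running_mean"].copy()
                layer.running_var = entry["_running_var"].copy()


class Adam:
    """Adam with the conventional defaults beta1=0.9, beta2=0.999, eps=1e-8."""

    def __init__(self, model: Model, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.model.layers):
            for name, p in layer.params.items():
                g = layer.grads[name].astype(np.float32)
                key = (i, name)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(p)
                    self._v[key] = np.zeros_like(p)
                v = self._v[key]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._m[key], self._v[key] = m, v
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                layer.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
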