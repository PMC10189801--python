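"""Minimal NumPy feed-forward/convolutional network with hand-written backprop.

Only what the classifiers here need: 1D convolution (stride 1, no padding),
dense layers, ReLU, inverted dropout, a sigmoid output trained with binary
cross-entropy on the logit, and plain SGD with optional momentum.  Keeping
the graph explicit also makes Grad-CAM a one-liner: activations and their
gradients are cached on the layers.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class Layer:
    """Base layer; parameters and their gradients live in dicts."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1D(Layer):
    """Cross-correlation over the position axis; input (B, L, C_in)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, std, (fan_in, out_channels)
                                      ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        k = self.kernel_size
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # (B, L', C, k) -> (B, L', k*C) matching W's (k, C) flattening
        xcol = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)
                                    ).reshape(B, L - k + 1, k * C)
        self._xcol = xcol
        self._in_shape = x.shape
        return xcol @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        B, L, C = self._in_shape
        k = self.kernel_size
        Lp = L - k + 1
        xcol2 = self._xcol.reshape(-1, k * C)
        dout2 = dout.reshape(-1, self.out_channels)
        self.grads["W"] = (xcol2.T @ dout2) / 1.0
        self.grads["b"] = dout2.sum(axis=0)
        dxcol = (dout2 @ self.params["W"].T).reshape(B, Lp, k, C)
        dx = np.zeros((B, L, C), dtype=dout.dtype)
        for j in range(k):
            dx[:, j:j + Lp, :] += dxcol[:, :, j, :]
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, relu_fan: bool = True) -> None:
        super().__init__()
        std = np.sqrt((2.0 if relu_fan else 1.0) / in_features)
        self.params["W"] = rng.normal(0.0, std, (in_features, out_features)
                                      ).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        self.output = x * self._mask
        return self.output

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask: Optional[np.ndarray] = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    """A stack of layers producing a single logit per example."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the input of
        ``layers[stop_at]`` (the network input when ``stop_at`` is 0)."""
        for i in reversed(range(stop_at, len(self.layers))):
            dout = self.layers[i].backward(dout)
        return dout

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def state(self) -> List[Dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self.layers]

    def load_state(self, state: List[Dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, state):
            for k, v in params.items():
                layer.params[k] = v.copy()

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


class TwoBranch:
    """Conv trunk on the window matrix, concatenated with a flat side vector,
    followed by a dense head.  Used by the combined classifier."""

    def __init__(self, trunk: Sequence[Layer], head: Sequence[Layer]) -> None:
        self.trunk = Sequential(trunk)
        self.head = Sequential(head)
        self._split: int = 0

    def forward(self, inputs: Tuple[np.ndarray, np.ndarray],
                train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        x, v = inputs
        t = self.trunk.forward(x, train=train, rng=rng)
        self._split = t.shape[1]
        return self.head.forward(np.concatenate([t, v], axis=1),
                                 train=train, rng=rng)

    def backward(self, dout: np.ndarray, stop_at: int = 0) -> np.ndarray:
        dcat = self.head.backward(dout)
        return self.trunk.backward(dcat[:, :self._split], stop_at=stop_at)

    @property
    def layers(self) -> List[Layer]:
        return self.trunk.layers + self.head.layers

    @property
    def n_params(self) -> int:
        return self.trunk.n_params + self.head.n_params

    def state(self):
        return self.trunk.state() + self.head.state()

    def load_state(self, state):
        k = len(self.trunk.layers)
        self.trunk.load_state(state[:k])
        self.head.load_state(state[k:])

    def parameters(self):
        yield from self.trunk.parameters()
        yield from self.head.parameters()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray
                    ) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / len(y)
    return loss, dz.astype(np.float32)


class SGD:
    def __init__(self, model, lr: float, momentum: float = 0.0) -> None:
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._velocity: Dict[Tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for layer, name in self.model.parameters():
            grad = layer.grads[name]
            if self.momentum:
                key = (id(layer), name)
                v = self._velocity.get(key)
                v = grad if v is None else self.momentum * v + grad
                self._velocity[key] = v
                grad = v
            layer.params[name] -= self.lr * grad
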