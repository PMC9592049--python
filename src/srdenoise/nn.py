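"""Minimal CNN engine for the denoising autoencoder.

Implements exactly the layer set the autoencoder needs — same-padded 2-D
convolution (im2col + matmul), ReLU, 2x average pooling, 2x nearest
upsampling — with reverse-mode gradients and an Adam optimizer. All math is
float32 numpy; determinism follows from seeded initialization and a fixed
iteration order.
"""

from __future__ import annotations

from typing import Iterator, List

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self) -> Iterator[dict]:
        return iter(())


class Conv2D(Layer):
    """k x k convolution with zero padding preserving spatial size.

    Weights are He-normal initialized; stored flat as (c_in*k*k, c_out) so
    forward/backward are single matmuls over im2col patches.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("filter size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.weight = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.weight + self.bias
        self._cols, self._shape = cols, (n, c, h, w)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1), dtype=np.float32).reshape(n * h * w, self.c_out)
        self.grad_weight = self._cols.T @ g
        self.grad_bias = g.sum(axis=0)
        dcols = (g @ self.weight.T).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]

    def parameters(self) -> Iterator[dict]:
        yield {"layer": self, "name": "weight"}
        yield {"layer": self, "name": "bias"}


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class AvgPool2(Layer):
    """2x2 average pooling (spatial downsampling by 2)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) * 0.25


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def conv_layers(self) -> List[Conv2D]:
        return [l for l in self.layers if isinstance(l, Conv2D)]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.conv_layers())

    def get_weights(self) -> List[np.ndarray]:
        out = []
        for l in self.conv_layers():
            out.extend([l.weight.copy(), l.bias.copy()])
        return out

    def set_weights(self, weights: List[np.ndarray]) -> None:
        convs = self.conv_layers()
        if len(weights) != 2 * len(convs):
            raise ValueError("weight list length mismatch")
        for i, l in enumerate(convs):
            l.weight = weights[2 * i].astype(np.float32).copy()
            l.bias = weights[2 * i + 1].astype(np.float32).copy()


class Adam:
    """Adam with standard bias correction over a Sequential's conv params."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr, self.beta1, self.beta2, self.eps = model, lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(getattr(p["layer"], p["name"])) for l in model.conv_layers() for p in l.parameters()]
        self._v = [np.zeros_like(m) for m in self._m]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.model.conv_layers():
            for p in layer.parameters():
                name = p["name"]
                g = getattr(layer, f"grad_{name}")
                self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
                self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g * g
                m_hat = self._m[i] / (1 - self.beta1**self.t)
                v_hat = self._v[i] / (1 - self.beta2**self.t)
                updated = getattr(layer, name) - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
                setattr(layer, name, updated.astype(np.float32))
                i += 1
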