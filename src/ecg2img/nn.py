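"""Minimal CPU neural-network layers with exact manual backpropagation.

This is the numerical core behind the classifier harness: 2-D and 1-D
convolutions (stride 1, 'same' padding), max pooling, ReLU, global
average pooling, dense layers, softmax cross-entropy and Adam. Everything
is plain single-precision numpy, seeded and fully deterministic, and every layer
caches what its backward pass needs — which is also what makes
gradient-based attribution (GradCAM) exact rather than approximate.

Shapes follow the NCHW / NCL convention. Layers are composed with
:class:`Sequential`; a layer's ``trainable`` flag controls whether the
optimizer updates it (frozen layers still propagate gradients).
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .errors import ShapeError


#: Working precision of the framework. Single precision halves memory
#: traffic, which dominates CPU conv cost; all contracts hold at 1e-6.
DTYPE = np.float32


class Layer:
    trainable: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """2-D convolution, zero 'same' padding, optional stride, He init."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 trainable: bool = True):
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.kernel = kernel
        self.stride = stride
        self.trainable = trainable
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.kernel // 2
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        p = k // 2
        ho, wo = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        views = [xp[:, :, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s]
                 for i, j in product(range(k), range(k))]
        # (N, C, k*k, Ho, Wo) -> (N, C*k*k, Ho*Wo); kk index varies fastest
        cols = np.stack(views, axis=2).reshape(n, c * k * k, ho * wo)
        self._cols = cols
        self._x_shape = x.shape
        w2 = self.w.reshape(self.w.shape[0], -1)
        out = np.matmul(w2, cols) + self.b[None, :, None]
        return out.reshape(n, self.w.shape[0], ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, ho, wo = grad.shape
        k, s = self.kernel, self.stride
        p = k // 2
        _, c_in, h, w = self._x_shape
        g = grad.reshape(n, c_out, ho * wo)
        cols = self._cols
        self.dw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0) \
            .reshape(self.w.shape)
        self.db = g.sum(axis=(0, 2))
        w2 = self.w.reshape(c_out, -1)
        dcols = np.matmul(w2.T, g).reshape(n, c_in, k * k, ho, wo)
        dxp = np.zeros((n, c_in, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for idx, (i, j) in enumerate(product(range(k), range(k))):
            dxp[:, :, i:i + s * (ho - 1) + 1:s,
                j:j + s * (wo - 1) + 1:s] += dcols[:, :, idx]
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Conv1D(Layer):
    """1-D convolution over (N, C, L), stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, trainable: bool = True):
        fan_in = c_in * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.kernel = kernel
        self.trainable = trainable
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.stack([xp[:, :, i:i + length] for i in range(k)], axis=2)
        cols = cols.reshape(n, c * k, length)
        self._cols = cols
        self._x_shape = x.shape
        w2 = self.w.reshape(self.w.shape[0], -1)
        return np.matmul(w2, cols) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, length = grad.shape
        k = self.kernel
        p = k // 2
        c_in = self._x_shape[1]
        self.dw = np.matmul(grad, self._cols.transpose(0, 2, 1)).sum(axis=0) \
            .reshape(self.w.shape)
        self.db = grad.sum(axis=(0, 2))
        w2 = self.w.reshape(c_out, -1)
        dcols = np.matmul(w2.T, grad).reshape(n, c_in, k, length)
        dxp = np.zeros((n, c_in, length + 2 * p), dtype=grad.dtype)
        for i in range(k):
            dxp[:, :, i:i + length] += dcols[:, :, i]
        return dxp[:, :, p:p + length]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; spatial dims must divide the size."""

    trainable = False

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ShapeError(f"pool size {s} does not divide {h}x{w}")
        xr = x.reshape(n, c, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        s = self.size
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(n, c, h, w)


class MaxPool1D(Layer):
    trainable = False

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        s = self.size
        trim = length - length % s
        self._length = length
        xr = x[:, :, :trim].reshape(n, c, trim // s, s)
        out = xr.max(axis=3)
        self._mask = xr == out[:, :, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, lout = grad.shape
        g = (grad[:, :, :, None] * self._mask).reshape(n, c, lout * self.size)
        out = np.zeros((n, c, self._length), dtype=grad.dtype)
        out[:, :, :lout * self.size] = g
        return out


class GlobalAvgPool(Layer):
    """(N, C, ...) -> (N, C): mean over all trailing spatial axes."""

    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape = self._x_shape
        n_spatial = int(np.prod(shape[2:]))
        g = np.broadcast_to(
            grad.reshape(shape[0], shape[1], *([1] * (len(shape) - 2))), shape)
        return (g / n_spatial).copy()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 trainable: bool = True):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.trainable = trainable
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential:
    """A simple layer chain with forward, backward and parameter access."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray, down_to: int = 0) -> np.ndarray:
        """Propagate ``grad`` backwards; stop after layer index ``down_to``.

        Returns the gradient with respect to the *input* of layer
        ``down_to`` (i.e. the output of layer ``down_to - 1``).
        """
        for layer in reversed(self.layers[down_to:]):
            grad = layer.backward(grad)
        return grad

    def trainable_params(self) -> list[np.ndarray]:
        return [p for l in self.layers if l.trainable for p in l.params()]

    def trainable_grads(self) -> list[np.ndarray]:
        return [g for l in self.layers if l.trainable for g in l.grads()]

    def all_params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def trainable_parameter_count(self) -> int:
        return sum(p.size for p in self.trainable_params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
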