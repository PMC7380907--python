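"""Minimal numpy neural-network engine used by the E-GONet classifier.

Implements exactly the layers the model needs — 3x3 same-padding
convolution, ReLU, 2x2 max-pooling, dense layers and inverted dropout —
with explicit backpropagation, so training is dependency-free and the
input gradient needed for gradient*input attribution is exact.

All randomness flows through a ``numpy.random.Generator``; with a fixed
seed, training is bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "ReLU", "MaxPool2", "Flatten", "Dense", "Dropout",
           "Sequential", "softmax", "cross_entropy", "Adam", "SGD"]


class Layer:
    params: tuple = ()

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution with same padding, stride 1 (im2col + matmul)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * 9))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, 3, 3))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = ((self.W, self.dW), (self.b, self.db))

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((B, 9 * C, H * W))
        for k in range(9):
            di, dj = divmod(k, 3)
            cols[:, k * C:(k + 1) * C, :] = (
                xp[:, :, di:di + H, dj:dj + W].reshape(B, C, H * W)
            )
        self.cols = cols
        self.in_shape = x.shape
        # W2[o, k*C + c] = W[o, c, di, dj] with k = di*3 + dj
        W2 = self.W.transpose(0, 2, 3, 1).reshape(self.W.shape[0], 9 * C)
        out = np.matmul(W2, cols)  # (B, O, H*W)
        out += self.b[None, :, None]
        return out.reshape(B, -1, H, W)

    def backward(self, grad):
        B, C, H, W = self.in_shape
        O = self.W.shape[0]
        g2 = grad.reshape(B, O, H * W)
        W2 = self.W.transpose(0, 2, 3, 1).reshape(O, 9 * C)
        dW2 = np.tensordot(g2, self.cols, axes=([0, 2], [0, 2]))
        self.dW[...] = dW2.reshape(O, 3, 3, C).transpose(0, 3, 1, 2)
        self.db[...] = g2.sum(axis=(0, 2))
        dcols = np.matmul(W2.T, g2)  # (B, 9C, H*W)
        dxp = np.zeros((B, C, H + 2, W + 2))
        for k in range(9):
            di, dj = divmod(k, 3)
            dxp[:, :, di:di + H, dj:dj + W] += (
                dcols[:, k * C:(k + 1) * C, :].reshape(B, C, H, W)
            )
        return dxp[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x, train=False):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        self.in_shape = x.shape
        H2, W2 = H // 2, W // 2
        xw = (
            x[:, :, : H2 * 2, : W2 * 2]
            .reshape(B, C, H2, 2, W2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H2, W2, 4)
        )
        self.arg = xw.argmax(axis=-1)
        return np.take_along_axis(xw, self.arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, C, H, W = self.in_shape
        H2, W2 = H // 2, W // 2
        dxw = np.zeros((B, C, H2, W2, 4))
        np.put_along_axis(dxw, self.arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self.in_shape)
        dx[:, :, : H2 * 2, : W2 * 2] = (
            dxw.reshape(B, C, H2, W2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H2 * 2, W2 * 2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = ((self.W, self.dW), (self.b, self.db))

    def forward(self, x, train=False):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self.x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep) / keep
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        """Backpropagate; returns the gradient with respect to the input."""
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [pg for layer in self.layers for pg in getattr(layer, "params", ())]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2):
        self.params = params
        self.lr = lr

    def step(self):
        for p, g in self.params:
            p -= self.lr * g
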