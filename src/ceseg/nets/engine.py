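"""Minimal NumPy layer/backprop engine for the two segmentation networks.

Dense/convolutional layers with explicit forward and backward passes, NHWC
layout.  Each layer instance caches what its backward pass needs, so a
layer object is used once per forward/backward cycle (one training step).
Weights are initialised Glorot-uniform from a seeded generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "Identity",
    "Dropout",
    "MaxPool2",
    "SubsamplePool2",
    "GlobalAvgPool",
    "Dense",
    "softmax",
    "cross_entropy_soft",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """k x k 'same'-padded convolution, stride 1, NHWC."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        self.W = Param(_glorot_uniform(rng, (k, k, cin, cout), k * k * cin, k * k * cout))
        self.b = Param(np.zeros(cout))
        # asymmetric 'same' padding for even kernels
        self.pl = (k - 1) // 2
        self.pr = k - 1 - self.pl

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pl, self.pr), (self.pl, self.pr), (0, 0)))
        self._xp, self._hw = xp, (h, w)
        out = np.broadcast_to(self.b.value, (n, h, w, len(self.b.value))).copy()
        for dy in range(self.k):
            for dx in range(self.k):
                out += xp[:, dy : dy + h, dx : dx + w, :] @ self.W.value[dy, dx]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        xp = self._xp
        dxp = np.zeros_like(xp)
        for dy in range(self.k):
            for dx in range(self.k):
                patch = xp[:, dy : dy + h, dx : dx + w, :]
                self.W.grad[dy, dx] += np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, dy : dy + h, dx : dx + w, :] += g @ self.W.value[dy, dx].T
        self.b.grad += g.sum(axis=(0, 1, 2))
        return dxp[:, self.pl : self.pl + h, self.pl : self.pl + w, :]


class ConvTranspose2d(Layer):
    """Stride-2 transposed convolution: zero-insertion upsampling + conv.

    Output is exactly 2H x 2W; with kernel 4 the filter footprints overlap
    evenly, avoiding the checkerboard artefact of kernels not divisible by
    the stride.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, k, rng)

    def params(self):
        return self.conv.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        up = np.zeros((n, 2 * h, 2 * w, c), dtype=x.dtype)
        up[:, ::2, ::2, :] = x
        return self.conv.forward(up, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        dup = self.conv.backward(g)
        return dup[:, ::2, ::2, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Identity(Layer):
    """Linear activation used by the receptive-field probe."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        gr = g[:, :, None, :, None, :] * self._mask
        return gr.reshape(self._shape)


class SubsamplePool2(Layer):
    """Stride-2 subsampling (no kernel extent).

    Stands in for max pooling in the linear receptive-field probe: the
    receptive-field convention counts a 2x2 pool as stride only, so the
    probe's downsampling must contribute no spatial support of its own.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, ::2, ::2, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = np.zeros(self._shape, dtype=g.dtype)
        out[:, ::2, ::2, :] = g
        return out


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = Param(_glorot_uniform(rng, (cin, cout), cin, cout))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_soft(
    logits: np.ndarray,
    p_edge: np.ndarray,
    class_weights: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Cross-entropy with soft targets (p_edge, 1 - p_edge).

    Channel 0 is the body class, channel 1 the edge class.  Returns the
    mean loss and its gradient with respect to the logits.  Optional class
    weighting multiplies the two target terms by (w_body, w_edge),
    normalised so the expected weight is comparable to the unweighted loss.
    """
    if logits.shape[-1] != 2:
        raise ValueError("expected 2-class logits")
    p_edge = np.asarray(p_edge, dtype=float)
    q = softmax(logits)
    logq = np.log(np.clip(q, 1e-12, None))
    t = np.stack([1.0 - p_edge, p_edge], axis=-1)
    if class_weights is None:
        w = np.ones_like(t)
    else:
        w = np.empty_like(t)
        w[..., 0], w[..., 1] = class_weights[0], class_weights[1]
        w = w / np.mean(np.sum(w * t, axis=-1))
    count = t[..., 0].size
    loss = -np.sum(w * t * logq) / count
    # d/dz_k of -(sum_j w_j t_j log q_j) = (sum_j w_j t_j) q_k - w_k t_k
    s = np.sum(w * t, axis=-1, keepdims=True)
    grad = (s * q - w * t) / count
    return float(loss), grad


class Adam:
    """Adam with the decaying learning-rate schedule lr_i = lr_{i-1}/(1 + decay * i)."""

    def __init__(
        self,
        params: list[Param],
        lr0: float = 1e-3,
        decay: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr0
        self.decay = decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.i = 0  # iteration counter
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> float:
        """Apply one update; returns the learning rate used."""
        self.i += 1
        self.lr = self.lr / (1.0 + self.decay * self.i)
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.i)
            vhat = v / (1 - b2**self.i)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return self.lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
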