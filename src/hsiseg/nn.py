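"""Minimal numpy neural-network engine for the patch-based framework.

Implements exactly the layer set the segmentation networks need — 3D and 2D
convolutions (full, depthwise and pointwise), spatial max-pooling, nearest
upsampling, spectral collapse, ReLU/sigmoid, inverted dropout — with
hand-written backward passes, plus Adam and RMSProp optimizers. Forward
passes use explicit kernel-offset loops (one matmul per offset), which keeps
memory flat and handles even-sized spectral kernels with asymmetric "same"
padding correctly.

Everything is deterministic given the RNG handed to the layers: parameter
initialisation and dropout draw from seeded generators only, so training
runs reproduce bit-for-bit on one CPU thread.

Tensor layout: ``(batch, height, width[, depth], channels)`` with the
spectral axis as depth.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "PointwiseConv", "DepthwiseConv3D", "Conv3D", "Conv2D",
    "ReLU", "Sigmoid", "Dropout", "MaxPool2x2", "Upsample2x",
    "SpectralCollapse", "Adam", "RMSProp", "n_parameters",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


def _same_pad(k: int) -> tuple[int, int]:
    # asymmetric for even kernels: left gets the smaller half
    return (k - 1) // 2, k // 2


class Layer:
    """Base layer: ``params``/``grads`` lists plus a ``trainable`` flag."""

    trainable: bool = True

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0


# --------------------------------------------------------------------------
# Convolutions
# --------------------------------------------------------------------------

class PointwiseConv(Layer):
    """1x1(x1) convolution: a channel-mixing matmul over any spatial rank."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _he_init(rng, (c_in, c_out), c_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.grads[0][...] = np.tensordot(self._x, grad,
                                          axes=(axes, axes))
        self.grads[1][...] = grad.sum(axis=axes)
        return grad @ self.w.T


class _OffsetConv(Layer):
    """Shared machinery: stride-1 'same' convolution via offset loops."""

    def __init__(self, kernel_shape: tuple[int, ...]):
        super().__init__()
        self.kshape = kernel_shape
        self.pads = [_same_pad(k) for k in kernel_shape]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        pad = [(0, 0)] + list(self.pads) + [(0, 0)]
        return np.pad(x, pad)

    def _slices(self, offset: tuple[int, ...],
                spatial: tuple[int, ...]) -> tuple[slice, ...]:
        return tuple(slice(o, o + s) for o, s in zip(offset, spatial))


class Conv3D(_OffsetConv):
    """Full 3-D convolution, kernel ``(kh, kw, kd)``, stride 1, same pad."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__(kernel)
        fan_in = c_in * int(np.prod(kernel))
        self.w = _he_init(rng, (*kernel, c_in, c_out), fan_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._xp = self._pad(x)
        spatial = x.shape[1:-1]
        out = np.zeros((*x.shape[:-1], self.w.shape[-1]))
        for off in np.ndindex(*self.kshape):
            sl = (slice(None), *self._slices(off, spatial), slice(None))
            out += self._xp[sl] @ self.w[off]
        self._spatial = spatial
        return out + self.b

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        dxp = np.zeros_like(self._xp)
        for off in np.ndindex(*self.kshape):
            sl = (slice(None), *self._slices(off, self._spatial), slice(None))
            self.grads[0][off] = np.tensordot(self._xp[sl], grad,
                                              axes=(axes, axes))
            dxp[sl] += grad @ self.w[off].T
        self.grads[1][...] = grad.sum(axis=axes)
        crop = (slice(None),
                *(slice(l, l + s) for (l, _), s in zip(self.pads,
                                                       self._spatial)),
                slice(None))
        return dxp[crop]


class DepthwiseConv3D(_OffsetConv):
    """Per-channel 3-D convolution, kernel ``(kh, kw, kd)`` applied to each
    channel independently (the depthwise half of a separable convolution)."""

    def __init__(self, channels: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__(kernel)
        fan_in = int(np.prod(kernel))
        self.w = _he_init(rng, (*kernel, channels), fan_in)
        self.b = np.zeros(channels)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._xp = self._pad(x)
        spatial = x.shape[1:-1]
        out = np.zeros_like(x)
        for off in np.ndindex(*self.kshape):
            sl = (slice(None), *self._slices(off, spatial), slice(None))
            out += self._xp[sl] * self.w[off]
        self._spatial = spatial
        return out + self.b

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        dxp = np.zeros_like(self._xp)
        for off in np.ndindex(*self.kshape):
            sl = (slice(None), *self._slices(off, self._spatial), slice(None))
            self.grads[0][off] = (self._xp[sl] * grad).sum(axis=axes)
            dxp[sl] += grad * self.w[off]
        self.grads[1][...] = grad.sum(axis=axes)
        crop = (slice(None),
                *(slice(l, l + s) for (l, _), s in zip(self.pads,
                                                       self._spatial)),
                slice(None))
        return dxp[crop]


class Conv2D(_OffsetConv):
    """Full 2-D convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__(kernel)
        fan_in = c_in * int(np.prod(kernel))
        self.w = _he_init(rng, (*kernel, c_in, c_out), fan_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    forward = Conv3D.forward
    backward = Conv3D.backward


# --------------------------------------------------------------------------
# Nonlinearities, dropout, pooling, resampling
# --------------------------------------------------------------------------

class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` and rate > 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool2x2(Layer):
    """2x2/stride-2 max pooling over the first two spatial axes; any rank."""

    def forward(self, x, train=False):
        b, h, w = x.shape[:3]
        rest = x.shape[3:]
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(b, h // 2, 2, w // 2, 2, *rest)
        out = xr.max(axis=(2, 4))
        # tie-splitting mask (grad shared across tied maxima)
        mask = xr == out[:, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4),
                                                keepdims=True), 1)
        self._shape = x.shape
        return out

    def backward(self, grad):
        b, h, w = self._shape[:3]
        rest = self._shape[3:]
        g = grad[:, :, None, :, None] * self._mask
        return g.reshape(self._shape)


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling on the first two spatial axes."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        b, h, w = self._shape[:3]
        rest = self._shape[3:]
        gr = grad.reshape(b, h, 2, w, 2, *rest)
        return gr.sum(axis=(2, 4))


class SpectralCollapse(Layer):
    """Drop the spectral axis (axis 3) by max or mean."""

    def __init__(self, mode: str = "max"):
        super().__init__()
        if mode not in ("max", "mean"):
            raise ValueError("collapse mode must be 'max' or 'mean'")
        self.mode = mode

    def forward(self, x, train=False):
        self._shape = x.shape
        if self.mode == "mean":
            return x.mean(axis=3)
        self._idx = x.argmax(axis=3)
        return np.take_along_axis(x, self._idx[:, :, :, None], axis=3)[
            :, :, :, 0]

    def backward(self, grad):
        dx = np.zeros(self._shape)
        if self.mode == "mean":
            dx += grad[:, :, :, None] / self._shape[3]
        else:
            np.put_along_axis(dx, self._idx[:, :, :, None],
                              grad[:, :, :, None], axis=3)
        return dx


# --------------------------------------------------------------------------
# Optimizers
# --------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, layers: list[Layer], lr: float, decay: float = 0.0):
        self.layers = [l for l in layers if l.params and l.trainable]
        self.lr = lr
        self.decay = decay
        self.t = 0

    def _current_lr(self) -> float:
        # exponential decay per step
        return self.lr * np.exp(-self.decay * self.t) if self.decay else self.lr

    def step(self) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, layers, lr, decay=0.0, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        super().__init__(layers, lr, decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        lr = self._current_lr()
        b1, b2 = self.beta1, self.beta2
        corr = lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                p -= corr * m / (np.sqrt(v) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, layers, lr, decay=0.0, rho=0.9, eps=1e-8):
        super().__init__(layers, lr, decay)
        self.rho, self.eps = rho, eps
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        lr = self._current_lr()
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                v = self.v[li][pi]
                v[...] = self.rho * v + (1 - self.rho) * g * g
                p -= lr * g / (np.sqrt(v) + self.eps)


def n_parameters(layers: list[Layer]) -> int:
    return sum(p.size for l in layers for p in l.params)
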