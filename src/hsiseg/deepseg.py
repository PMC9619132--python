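"""Patch-based deep segmentation framework.

Networks operate on hyperspectral patches ``(batch, H, W, bands)`` and emit
per-pixel tumor probabilities ``(batch, H, W, 1)`` through a sigmoid head.

* ``xception3d`` — an encoder of depthwise-separable 3D-convolution blocks
  (depthwise spatial x spectral kernel, then pointwise channel mixing; two
  separable convolutions plus a residual shortcut per block; x2 spatial
  max-pooling and 40% dropout at each block end). The spectral axis is kept
  intact through the encoder and dropped at the bottleneck by a max or mean
  collapse; a 2D decoder mirrors the encoder with x2 upsampling and skip
  connections taken from spectrally-collapsed encoder features.
* ``unet3d`` — a plain 3D-convolution U-Net baseline with the same spectral
  collapse at the bottleneck and the same 2D decoder.
* ``resnet_pretrained`` / ``resnet_custom`` — 2D residual networks behind a
  trainable convolution that reduces the spectral channels to 3. The
  pretrained variant freezes the residual body (random weights are used when
  no pretrained weight file is available offline, flagged in the model
  metadata); the custom variant trains everything from scratch.

Losses: pixel-mean binary cross-entropy, the soft Jaccard loss
``1 - sum(PR*GT) / (sum(PR) + sum(GT) - sum(PR*GT))``, and their sum
(BCE+JC), which counteracts class imbalance between tumor and normal
pixels. Training supports Adam and RMSProp with optional exponential decay
and is deterministic per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .preprocess import PatchSet

__all__ = [
    "NetworkConfig", "TrainConfig", "PatchPrediction",
    "bce_loss", "jaccard_loss", "bce_jc_loss",
    "build_network", "train_model", "predict_patchset", "grid_search_train",
]

PROB_CLIP = 1e-7
JC_SMOOTH = 1e-7

ARCHS = ("xception3d", "unet3d", "resnet_pretrained", "resnet_custom")


@dataclass(frozen=True)
class NetworkConfig:
    arch: str = "xception3d"
    n_blocks: int = 3
    filters: tuple[int, ...] = (64, 128, 256)
    spatial_kernel: int = 3
    spectral_kernels: tuple[int, ...] = (10, 20, 20)
    bottleneck_collapse: str = "max"
    dropout_rate: float = 0.40
    input_shape: tuple[int, int, int] = (32, 32, 311)
    # resnet-specific knobs (ResNet-34 basic-block layout by default)
    resnet_blocks: tuple[int, ...] = (3, 4, 6, 3)
    resnet_base_width: int = 64

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}")
        if self.arch in ("xception3d", "unet3d"):
            if not (len(self.filters) == self.n_blocks
                    == len(self.spectral_kernels)):
                raise ValueError("filters and spectral_kernels must both "
                                 "have n_blocks entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.bottleneck_collapse not in ("max", "mean"):
            raise ValueError("bottleneck_collapse must be 'max' or 'mean'")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-5
    decay: float = 0.0
    loss: str = "bce_jc"
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("bce", "bce_jc"):
            raise ValueError("loss must be 'bce' or 'bce_jc'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class PatchPrediction:
    """Per-patch probability maps co-indexed with a PatchSet's originals."""

    probabilities: list[np.ndarray]

    def __post_init__(self) -> None:
        for p in self.probabilities:
            if p.ndim != 2:
                raise ValueError("each probability map must be 2-D")
            if p.min() < 0.0 or p.max() > 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# --------------------------------------------------------------------------
# Losses (values and gradients w.r.t. the probabilities)
# --------------------------------------------------------------------------

def _clip(pr: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(pr, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)


def _check_shapes(pr: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray,
                                                           np.ndarray]:
    pr = np.asarray(pr, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pr.shape != gt.shape:
        raise ValueError(f"PR shape {pr.shape} != GT shape {gt.shape}")
    return pr, gt


def bce_loss(pr: np.ndarray, gt: np.ndarray) -> float:
    """Binary cross-entropy, mean over pixels, probabilities clipped."""
    pr, gt = _check_shapes(pr, gt)
    p = _clip(pr)
    return float(np.mean(-gt * np.log(p) - (1 - gt) * np.log(1 - p)))


def _bce_grad(pr: np.ndarray, gt: np.ndarray) -> np.ndarray:
    p = _clip(pr)
    return (p - gt) / (p * (1 - p)) / pr.size


def jaccard_loss(pr: np.ndarray, gt: np.ndarray) -> float:
    """Soft Jaccard loss ``1 - I/U``; 0 for two empty masks (smoothed)."""
    pr, gt = _check_shapes(pr, gt)
    inter = float(np.sum(pr * gt))
    union = float(np.sum(pr) + np.sum(gt) - inter)
    return 1.0 - (inter + JC_SMOOTH) / (union + JC_SMOOTH)


def _jaccard_grad(pr: np.ndarray, gt: np.ndarray) -> np.ndarray:
    inter = np.sum(pr * gt) + JC_SMOOTH
    union = np.sum(pr) + np.sum(gt) - np.sum(pr * gt) + JC_SMOOTH
    return -(gt * union - inter * (1 - gt)) / union ** 2


def bce_jc_loss(pr: np.ndarray, gt: np.ndarray) -> float:
    """Composite loss: binary cross-entropy plus soft Jaccard."""
    return bce_loss(pr, gt) + jaccard_loss(pr, gt)


_LOSSES = {
    "bce": (bce_loss, _bce_grad),
    "bce_jc": (bce_jc_loss,
               lambda pr, gt: _bce_grad(pr, gt) + _jaccard_grad(pr, gt)),
}


# --------------------------------------------------------------------------
# Network definitions
# --------------------------------------------------------------------------

def _clip_spectral_kernels(kernels: Sequence[int], bands: int) -> list[int]:
    out = []
    for k in kernels:
        if k > bands:
            warnings.warn(f"spectral kernel {k} exceeds band depth {bands}; "
                          "clipping")
            k = bands
        out.append(int(k))
    return out


class _SegModel:
    """Common surface: forward, backward, weight snapshots, metadata."""

    config: NetworkConfig
    layers: list[nn.Layer]
    metadata: dict

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dprob: np.ndarray) -> None:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for l in self.layers:
            for p in l.params:
                p[...] = weights[i]
                i += 1

    def n_parameters(self) -> int:
        return nn.n_parameters(self.layers)


class _Decoder2D:
    """Shared x2-upsampling decoder with optional skip concatenation."""

    def __init__(self, in_ch: int, skips_ch: Sequence[int],
                 out_chs: Sequence[int], rng: np.random.Generator):
        # levels run deepest -> shallowest; skips_ch[i] == 0 means no skip
        self.ups, self.convs, self.relus = [], [], []
        self.skips_ch = list(skips_ch)
        ch = in_ch
        for c_skip, c_out in zip(skips_ch, out_chs):
            self.ups.append(nn.Upsample2x())
            self.convs.append(nn.Conv2D(ch + c_skip, c_out, (3, 3), rng))
            self.relus.append(nn.ReLU())
            ch = c_out
        self.out_ch = ch

    @property
    def layers(self) -> list[nn.Layer]:
        return [*self.ups, *self.convs, *self.relus]

    def forward(self, x: np.ndarray, skips: Sequence[np.ndarray | None],
                train: bool) -> np.ndarray:
        self._up_ch = []
        for up, conv, relu, skip in zip(self.ups, self.convs, self.relus,
                                        skips):
            x = up.forward(x, train)
            self._up_ch.append(x.shape[-1])
            if skip is not None:
                x = np.concatenate([x, skip], axis=-1)
            x = relu.forward(conv.forward(x, train), train)
        return x

    def backward(self, grad: np.ndarray
                 ) -> tuple[np.ndarray, list[np.ndarray | None]]:
        skip_grads: list[np.ndarray | None] = [None] * len(self.ups)
        for i in reversed(range(len(self.ups))):
            grad = self.convs[i].backward(self.relus[i].backward(grad))
            c_up = self._up_ch[i]
            if self.skips_ch[i]:
                skip_grads[i] = grad[..., c_up:]
                grad = grad[..., :c_up]
            grad = self.ups[i].backward(grad)
        return grad, skip_grads


class Xception3D(_SegModel):
    """Depthwise-separable 3D encoder + spectral collapse + 2D decoder."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        h, w, bands = config.input_shape
        n = config.n_blocks
        if h % (2 ** n) or w % (2 ** n):
            raise ValueError(f"patch size {h}x{w} not divisible by 2^{n}")
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        sk = _clip_spectral_kernels(config.spectral_kernels, bands)
        ksp = config.spatial_kernel
        f = list(config.filters)

        self.blocks = []
        c_in = 1
        for i in range(n):
            blk = {
                "dw1": nn.DepthwiseConv3D(c_in, (ksp, ksp, sk[i]), rng),
                "pw1": nn.PointwiseConv(c_in, f[i], rng),
                "relu1": nn.ReLU(),
                "dw2": nn.DepthwiseConv3D(f[i], (ksp, ksp, sk[i]), rng),
                "pw2": nn.PointwiseConv(f[i], f[i], rng),
                "proj": nn.PointwiseConv(c_in, f[i], rng),
                "relu2": nn.ReLU(),
                "skip_collapse": nn.SpectralCollapse(config.bottleneck_collapse),
                "pool": nn.MaxPool2x2(),
                "drop": nn.Dropout(config.dropout_rate, self.dropout_rng),
            }
            self.blocks.append(blk)
            c_in = f[i]
        self.bottleneck = nn.SpectralCollapse(config.bottleneck_collapse)
        self.decoder = _Decoder2D(f[-1], skips_ch=list(reversed(f)),
                                  out_chs=list(reversed(f)), rng=rng)
        self.head = nn.Conv2D(self.decoder.out_ch, 1, (1, 1), rng)
        self.sigmoid = nn.Sigmoid()
        self.layers = [l for blk in self.blocks for l in blk.values()] + \
            [self.bottleneck, *self.decoder.layers, self.head, self.sigmoid]
        self.metadata = {"arch": "xception3d", "seed": seed,
                         "spectral_kernels": sk}

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=float)[..., None]     # add channel axis
        skips = []
        for blk in self.blocks:
            inp = x
            y = blk["relu1"].forward(
                blk["pw1"].forward(blk["dw1"].forward(x, train), train), train)
            y = blk["pw2"].forward(blk["dw2"].forward(y, train), train)
            y = blk["relu2"].forward(y + blk["proj"].forward(inp, train),
                                     train)
            skips.append(blk["skip_collapse"].forward(y, train))
            x = blk["drop"].forward(blk["pool"].forward(y, train), train)
        z = self.bottleneck.forward(x, train)
        z = self.decoder.forward(z, list(reversed(skips)), train)
        return self.sigmoid.forward(self.head.forward(z, train), train)

    def backward(self, dprob):
        g = self.head.backward(self.sigmoid.backward(dprob))
        g, skip_grads = self.decoder.backward(g)
        g3 = self.bottleneck.backward(g)
        skip_grads = list(reversed(skip_grads))       # block order
        for i in reversed(range(len(self.blocks))):
            blk = self.blocks[i]
            g3 = blk["pool"].backward(blk["drop"].backward(g3))
            if skip_grads[i] is not None:
                g3 = g3 + 0.0   # ensure own buffer
            gy = g3
            if skip_grads[i] is not None:
                gy = gy + blk["skip_collapse"].backward(skip_grads[i])
            gy = blk["relu2"].backward(gy)
            g_sc = blk["proj"].backward(gy)
            gm = blk["dw2"].backward(blk["pw2"].backward(gy))
            gm = blk["relu1"].backward(gm)
            gm = blk["dw1"].backward(blk["pw1"].backward(gm))
            g3 = gm + g_sc
        # g3 is grad w.r.t. the (B,H,W,D,1) input; discarded


class UNet3D(_SegModel):
    """Plain 3D-convolution U-Net baseline with bottleneck collapse."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        h, w, bands = config.input_shape
        n = config.n_blocks
        if h % (2 ** n) or w % (2 ** n):
            raise ValueError(f"patch size {h}x{w} not divisible by 2^{n}")
        rng = np.random.default_rng(seed)
        sk = _clip_spectral_kernels(config.spectral_kernels, bands)
        ksp = config.spatial_kernel
        f = list(config.filters)
        self.blocks = []
        c_in = 1
        for i in range(n):
            blk = {
                "conv1": nn.Conv3D(c_in, f[i], (ksp, ksp, sk[i]), rng),
                "relu1": nn.ReLU(),
                "conv2": nn.Conv3D(f[i], f[i], (ksp, ksp, sk[i]), rng),
                "relu2": nn.ReLU(),
                "skip_collapse": nn.SpectralCollapse(config.bottleneck_collapse),
                "pool": nn.MaxPool2x2(),
            }
            self.blocks.append(blk)
            c_in = f[i]
        self.bottleneck = nn.SpectralCollapse(config.bottleneck_collapse)
        self.decoder = _Decoder2D(f[-1], skips_ch=list(reversed(f)),
                                  out_chs=list(reversed(f)), rng=rng)
        self.head = nn.Conv2D(self.decoder.out_ch, 1, (1, 1), rng)
        self.sigmoid = nn.Sigmoid()
        self.layers = [l for blk in self.blocks for l in blk.values()] + \
            [self.bottleneck, *self.decoder.layers, self.head, self.sigmoid]
        self.metadata = {"arch": "unet3d", "seed": seed,
                         "spectral_kernels": sk}

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=float)[..., None]
        skips = []
        for blk in self.blocks:
            x = blk["relu1"].forward(blk["conv1"].forward(x, train), train)
            x = blk["relu2"].forward(blk["conv2"].forward(x, train), train)
            skips.append(blk["skip_collapse"].forward(x, train))
            x = blk["pool"].forward(x, train)
        z = self.bottleneck.forward(x, train)
        z = self.decoder.forward(z, list(reversed(skips)), train)
        return self.sigmoid.forward(self.head.forward(z, train), train)

    def backward(self, dprob):
        g = self.head.backward(self.sigmoid.backward(dprob))
        g, skip_grads = self.decoder.backward(g)
        g3 = self.bottleneck.backward(g)
        skip_grads = list(reversed(skip_grads))
        for i in reversed(range(len(self.blocks))):
            blk = self.blocks[i]
            g3 = blk["pool"].backward(g3)
            if skip_grads[i] is not None:
                g3 = g3 + blk["skip_collapse"].backward(skip_grads[i])
            g3 = blk["conv2"].backward(blk["relu2"].backward(g3))
            g3 = blk["conv1"].backward(blk["relu1"].backward(g3))


class ResNetSeg(_SegModel):
    """2D residual network behind a spectral-reduction convolution.

    The spectral axis is treated as the channel axis of a 2D image; a 1x1
    convolution reduces it to 3 channels, followed by a stem convolution and
    residual stages of basic blocks (two 3x3 convolutions plus identity).
    ``frozen_body=True`` reproduces the transfer-learning configuration:
    only the reduction convolution and decoder head are trained.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0,
                 frozen_body: bool = False):
        self.config = config
        h, w, bands = config.input_shape
        n_down = max(len(config.resnet_blocks) - 1, 0)
        if h % (2 ** n_down) or w % (2 ** n_down):
            raise ValueError(f"patch size {h}x{w} not divisible by "
                             f"2^{n_down}")
        rng = np.random.default_rng(seed)
        bw = config.resnet_base_width
        widths = [bw * (2 ** s) for s in range(len(config.resnet_blocks))]

        self.reduce = nn.PointwiseConv(bands, 3, rng)
        self.stem = nn.Conv2D(3, widths[0], (3, 3), rng)
        self.stem_relu = nn.ReLU()
        self.stages = []
        ch = widths[0]
        for s, (n_blk, width) in enumerate(zip(config.resnet_blocks, widths)):
            stage = {"pool": nn.MaxPool2x2() if s > 0 else None,
                     "proj": nn.PointwiseConv(ch, width, rng)
                     if width != ch else None,
                     "blocks": []}
            ch = width
            for _ in range(n_blk):
                stage["blocks"].append({
                    "conv1": nn.Conv2D(ch, ch, (3, 3), rng),
                    "relu1": nn.ReLU(),
                    "conv2": nn.Conv2D(ch, ch, (3, 3), rng),
                    "relu2": nn.ReLU(),
                })
            self.stages.append(stage)
        self.decoder = _Decoder2D(ch, skips_ch=[0] * n_down,
                                  out_chs=[max(ch // (2 ** (i + 1)), 8)
                                           for i in range(n_down)], rng=rng)
        self.head = nn.Conv2D(self.decoder.out_ch, 1, (1, 1), rng)
        self.sigmoid = nn.Sigmoid()

        body = [self.stem, self.stem_relu]
        for st in self.stages:
            if st["pool"]:
                body.append(st["pool"])
            if st["proj"]:
                body.append(st["proj"])
            for blk in st["blocks"]:
                body.extend(blk.values())
        if frozen_body:
            for layer in body:
                layer.trainable = False
        self.layers = [self.reduce, *body, *self.decoder.layers, self.head,
                       self.sigmoid]
        self.metadata = {"arch": ("resnet_pretrained" if frozen_body
                                  else "resnet_custom"),
                         "seed": seed, "frozen_body": frozen_body,
                         "pretrained_weights_available": False}

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=float)       # (B, H, W, bands) as channels
        x = self.reduce.forward(x, train)
        x = self.stem_relu.forward(self.stem.forward(x, train), train)
        for st in self.stages:
            if st["pool"]:
                x = st["pool"].forward(x, train)
            if st["proj"]:
                x = st["proj"].forward(x, train)
            for blk in st["blocks"]:
                y = blk["relu1"].forward(blk["conv1"].forward(x, train),
                                         train)
                y = blk["conv2"].forward(y, train)
                x = blk["relu2"].forward(x + y, train)
        x = self.decoder.forward(x, [None] * len(self.decoder.ups), train)
        return self.sigmoid.forward(self.head.forward(x, train), train)

    def backward(self, dprob):
        g = self.head.backward(self.sigmoid.backward(dprob))
        g, _ = self.decoder.backward(g)
        for st in reversed(self.stages):
            for blk in reversed(st["blocks"]):
                gy = blk["relu2"].backward(g)
                gb = blk["conv1"].backward(
                    blk["relu1"].backward(blk["conv2"].backward(gy)))
                g = gy + gb
            if st["proj"]:
                g = st["proj"].backward(g)
            if st["pool"]:
                g = st["pool"].backward(g)
        g = self.stem.backward(self.stem_relu.backward(g))
        self.reduce.backward(g)


def build_network(config: NetworkConfig, seed: int = 0) -> _SegModel:
    """Build a segmentation network from its configuration (seeded init)."""
    if config.arch == "xception3d":
        return Xception3D(config, seed)
    if config.arch == "unet3d":
        return UNet3D(config, seed)
    if config.arch == "resnet_pretrained":
        return ResNetSeg(config, seed, frozen_body=True)
    return ResNetSeg(config, seed, frozen_body=False)


# --------------------------------------------------------------------------
# Training and prediction
# --------------------------------------------------------------------------

def _patchset_arrays(patchset: PatchSet, originals_only: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    idx = patchset.originals if originals_only else range(len(patchset))
    x = np.stack([patchset.patches[i] for i in idx])
    y = np.stack([patchset.labels[i] for i in idx]).astype(float)
    return x, y


def _binary_jc(pred: np.ndarray, gt: np.ndarray) -> float:
    p = pred >= 0.5
    g = gt >= 0.5
    union = np.sum(p | g)
    if union == 0:
        return 1.0
    return float(np.sum(p & g) / union)


def _eval_on(model: _SegModel, x: np.ndarray, y: np.ndarray,
             loss_fn, batch_size: int) -> tuple[float, float, np.ndarray]:
    losses, probs = [], []
    for s in range(0, len(x), batch_size):
        pr = model.forward(x[s:s + batch_size], train=False)[..., 0]
        losses.append(loss_fn(pr, y[s:s + batch_size]) * len(pr))
        probs.append(pr)
    probs = np.concatenate(probs)
    return float(np.sum(losses) / len(x)), _binary_jc(probs, y), probs


def train_model(model: _SegModel, train: PatchSet, val: PatchSet,
                config: TrainConfig) -> tuple[_SegModel, dict]:
    """Seeded training loop; returns the model at its best-validation-JC
    weights and a per-epoch history (train/val loss and val JC)."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation patch sets must be non-empty")
    x_train, y_train = _patchset_arrays(train)
    x_val, y_val = _patchset_arrays(val)
    loss_fn, grad_fn = _LOSSES[config.loss]
    opt_cls = {"adam": nn.Adam, "rmsprop": nn.RMSProp}[config.optimizer]
    optimizer = opt_cls(model.layers, lr=config.learning_rate,
                        decay=config.decay)
    rng = np.random.default_rng(config.seed)

    history = {"train_loss": [], "val_loss": [], "val_jc": []}
    best_jc, best_weights = -1.0, model.get_weights()
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for s in range(0, len(order), config.batch_size):
            batch = order[s:s + config.batch_size]
            pr = model.forward(x_train[batch], train=True)[..., 0]
            loss = loss_fn(pr, y_train[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {s // config.batch_size}: "
                    f"{loss}; lr={config.learning_rate}")
            model.zero_grads()
            model.backward(grad_fn(pr, y_train[batch])[..., None])
            optimizer.step()
            epoch_losses.append(loss * len(batch))
        train_loss = float(np.sum(epoch_losses) / len(x_train))
        val_loss, val_jc, _ = _eval_on(model, x_val, y_val, loss_fn,
                                       config.batch_size)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["val_jc"].append(val_jc)
        if val_jc > best_jc:
            best_jc = val_jc
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    history["best_val_jc"] = best_jc
    return model, history


def predict_patchset(model: _SegModel, patchset: PatchSet,
                     batch_size: int = 8) -> PatchPrediction:
    """Probability maps for the original (non-augmented) patches, in order;
    composable with :func:`hsiseg.preprocess.stitch_patches`."""
    idx = patchset.originals
    probs = []
    for s in range(0, len(idx), batch_size):
        batch = np.stack([patchset.patches[i] for i in idx[s:s + batch_size]])
        if batch.shape[1:3] != tuple(model.config.input_shape[:2]):
            raise ValueError(
                f"patch size {batch.shape[1:3]} does not match model input "
                f"{model.config.input_shape[:2]}")
        pr = model.forward(batch, train=False)[..., 0]
        probs.extend(np.clip(p, 0.0, 1.0) for p in pr)
    return PatchPrediction(probabilities=probs)


def grid_search_train(configs: Sequence[tuple[NetworkConfig, TrainConfig]],
                      train: PatchSet, val: PatchSet,
                      seed: int = 0) -> tuple[pd.DataFrame, list[dict]]:
    """Train every (network, training) configuration with shared seeds and
    rank by validation JC, then by validation AUC."""
    if not configs:
        raise ValueError("need at least one configuration")
    from .evalkit import roc_auc

    results = []
    x_val, y_val = _patchset_arrays(val)
    for i, (net_cfg, train_cfg) in enumerate(configs):
        model = build_network(net_cfg, seed=seed)
        model, history = train_model(model, train, val, train_cfg)
        loss_fn, _ = _LOSSES[train_cfg.loss]
        _, val_jc, probs = _eval_on(model, x_val, y_val, loss_fn,
                                    train_cfg.batch_size)
        if len(np.unique(y_val >= 0.5)) > 1:
            auc = roc_auc(probs, (y_val >= 0.5).astype(int))
        else:
            auc = float("nan")
        results.append({"index": i, "arch": net_cfg.arch,
                        "optimizer": train_cfg.optimizer,
                        "learning_rate": train_cfg.learning_rate,
                        "loss": train_cfg.loss, "val_jc": val_jc,
                        "val_auc": auc, "model": model,
                        "history": history})
    table = pd.DataFrame([{k: v for k, v in r.items()
                           if k not in ("model", "history")}
                          for r in results])
    table = table.sort_values(["val_jc", "val_auc"],
                              ascending=False).reset_index(drop=True)
    order = list(table["index"])
    return table, [results[i] for i in order]
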