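"""Fully semantic segmentation network for retinal OCT B-scans.

A U-Net-style encoder--decoder classifies every pixel of a (padded)
B-scan into three regions -- vitreous + padding, retina, and
choroid + sclera -- whose two transitions are the ILM and the
RPE-base/Bruch's membrane.  Each resolution level is a residual block
of three ``conv 3x3 -> batch-norm -> ReLU`` units with the outputs of
the first and last units added; levels may be followed by a concurrent
spatial & channel squeeze-and-excitation (scSE) recalibration.  Eight
filters are used at the first level and doubled after every 2x2
max-pooling; the mirrored decoder upsamples with 2x2 stride-2
transposed convolutions and concatenates skip connections; a 50%
dropout regularizes the bottleneck; a final 1x1 convolution + softmax
yields per-pixel class probabilities.

The network is trained by minimizing soft Dice loss (see
:func:`dice_loss`); :func:`receptive_field` computes the analytic
effective receptive field of a configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

DICE_EPS = 1e-6

_SCSE_MODES = ("none", "cse", "sse", "scse")


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    n_pool: number of pooling layers (4 or 5).
    base_filters: filters at the first level; doubled after each pool.
    convs_per_level: convolution blocks per resolution level.
    kernel: convolution kernel side (square, same-padded).
    scse: squeeze-and-excitation variant at each level output
        ("none", "cse", "sse" or "scse").
    scse_reduction: channel reduction ratio of the cSE bottleneck.
    scse_combine: how the cSE and sSE recalibrations are merged
        ("max" or "sum").
    bottleneck_dropout: dropout probability at the bottleneck.
    upsample: decoder upsampling, "transpose" (2x2 stride-2 transposed
        convolution) or "nearest" (nearest-neighbour + 3x3 convolution).
    """

    n_pool: int = 4
    base_filters: int = 8
    convs_per_level: int = 3
    kernel: int = 3
    scse: str = "none"
    scse_reduction: int = 2
    scse_combine: str = "max"
    bottleneck_dropout: float = 0.5
    n_classes: int = 3
    upsample: str = "transpose"

    def __post_init__(self):
        if self.n_pool not in (4, 5):
            raise ValueError("n_pool must be 4 or 5")
        if self.scse not in _SCSE_MODES:
            raise ValueError(f"scse must be one of {_SCSE_MODES}")
        if self.scse_combine not in ("max", "sum"):
            raise ValueError("scse_combine must be 'max' or 'sum'")
        if self.upsample not in ("transpose", "nearest"):
            raise ValueError("upsample must be 'transpose' or 'nearest'")
        if self.base_filters < 1 or self.convs_per_level < 1:
            raise ValueError("base_filters and convs_per_level must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd (same padding)")

    @property
    def encoder_filters(self):
        """Filters per encoder level including the bottleneck."""
        return [self.base_filters * 2 ** L for L in range(self.n_pool + 1)]

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def receptive_field(cfg: NetConfig) -> int:
    """Effective receptive field side at the bottleneck output.

    Iterates ``r <- r + (k - 1) * j`` over the encoder's layers, where
    ``j`` is the cumulative stride product: each same-padded ``k x k``
    convolution grows ``r`` by ``(k - 1) * j``; each 2x2 stride-2 pool
    grows ``r`` by ``j`` and doubles ``j``.  Counts ``convs_per_level``
    convolutions per encoder level, one pool after each level, and the
    bottleneck convolutions.
    """
    r, j = 1, 1
    for _ in range(cfg.n_pool):
        r += cfg.convs_per_level * (cfg.kernel - 1) * j
        r += j  # 2x2 pool
        j *= 2
    r += cfg.convs_per_level * (cfg.kernel - 1) * j  # bottleneck convs
    return r


def dice_loss(probs, truth_onehot):
    """Soft Dice loss, ``1 - mean_c D_c`` with
    ``D_c = (2 sum(p t) + eps) / (sum(p) + sum(t) + eps)``.

    ``probs``: Tensor or array (N, C, H, W) of class probabilities;
    ``truth_onehot``: array (N, C, H, W) of one-hot ground truth.
    Returns a scalar Tensor in [0, 1] (differentiable if ``probs`` is
    part of a recorded graph).
    """
    probs = ag.astensor(probs)
    t = np.asarray(truth_onehot, dtype=np.float32)
    if probs.data.shape != t.shape:
        raise ValueError("probs and truth shapes differ")
    axes = (0, 2, 3)
    num = ag.add(ag.mul(ag.tsum(ag.mul(probs, t), axis=axes), 2.0), DICE_EPS)
    den = ag.add(ag.tsum(probs, axis=axes), t.sum(axis=axes) + DICE_EPS)
    dice_per_class = ag.div(num, den)
    return ag.sub(1.0, ag.tmean(dice_per_class))


class SCSEBlock(nn.Module):
    """Concurrent spatial & channel squeeze-and-excitation.

    cSE: global-average-pooled channel descriptor -> two fully connected
    layers (reduction ratio r) -> sigmoid gates scaling each channel.
    sSE: 1x1 convolution -> sigmoid gating each spatial location.
    The two recalibrated maps are combined element-wise (max or sum).
    """

    def __init__(self, channels, rng, mode="scse", reduction=2, combine="max"):
        self.mode = mode
        self.combine = combine
        if mode in ("cse", "scse"):
            r = reduction if channels >= reduction else 1
            self.fc1 = nn.Linear(channels, channels // r, rng)
            self.fc2 = nn.Linear(channels // r, channels, rng)
        if mode in ("sse", "scse"):
            self.spatial = nn.Conv2d(channels, 1, 1, rng)

    def _cse(self, x):
        n, c = x.data.shape[:2]
        desc = ag.tmean(x, axis=(2, 3))  # (N, C)
        gate = ag.sigmoid(self.fc2(ag.relu(self.fc1(desc))))
        return ag.mul(x, ag.reshape(gate, (n, c, 1, 1)))

    def _sse(self, x):
        return ag.mul(x, ag.sigmoid(self.spatial(x)))

    def __call__(self, x):
        if self.mode == "cse":
            return self._cse(x)
        if self.mode == "sse":
            return self._sse(x)
        a, b = self._cse(x), self._sse(x)
        return ag.maximum(a, b) if self.combine == "max" else ag.add(a, b)


def scse_block(features, block: SCSEBlock):
    """Apply an scSE block to a feature Tensor (functional form)."""
    return block(features)


class ResidualConvBlock(nn.Module):
    """``convs_per_level`` conv->BN->ReLU units; outputs of the first and
    last units are added (residual connection)."""

    def __init__(self, cin, cout, n_convs, kernel, rng):
        self.convs = [nn.Conv2d(cin if i == 0 else cout, cout, kernel, rng)
                      for i in range(n_convs)]
        self.bns = [nn.BatchNorm2d(cout) for _ in range(n_convs)]

    def __call__(self, x, training):
        first = None
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            x = ag.relu(bn(conv(x), training))
            if i == 0:
                first = x
        return ag.add(first, x) if len(self.convs) > 1 else x


class SegNet(nn.Module):
    """Encoder--decoder semantic segmentation network (see module docstring)."""

    def __init__(self, cfg: NetConfig, seed=0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        f = cfg.encoder_filters
        n, k = cfg.convs_per_level, cfg.kernel

        self.enc_blocks = [
            ResidualConvBlock(1 if L == 0 else f[L - 1], f[L], n, k, rng)
            for L in range(cfg.n_pool)
        ]
        self.bottleneck = ResidualConvBlock(f[cfg.n_pool - 1], f[cfg.n_pool], n, k, rng)

        self.up_convs = []
        self.dec_blocks = []
        for L in reversed(range(cfg.n_pool)):
            if cfg.upsample == "transpose":
                self.up_convs.append(nn.ConvTranspose2x2(f[L + 1], f[L], rng))
            else:
                self.up_convs.append(nn.Conv2d(f[L + 1], f[L], k, rng))
            self.dec_blocks.append(ResidualConvBlock(2 * f[L], f[L], n, k, rng))

        if cfg.scse != "none":
            self.enc_scse = [SCSEBlock(f[L], rng, cfg.scse, cfg.scse_reduction,
                                       cfg.scse_combine)
                             for L in range(cfg.n_pool)]
            self.bott_scse = SCSEBlock(f[cfg.n_pool], rng, cfg.scse,
                                       cfg.scse_reduction, cfg.scse_combine)
            self.dec_scse = [SCSEBlock(f[L], rng, cfg.scse, cfg.scse_reduction,
                                       cfg.scse_combine)
                             for L in reversed(range(cfg.n_pool))]
        else:
            self.enc_scse = self.bott_scse = self.dec_scse = None

        self.head = nn.Conv2d(f[0], cfg.n_classes, 1, rng)

    # -- forward ---------------------------------------------------------
    def check_input(self, h, w):
        d = 2 ** self.cfg.n_pool
        if h % d or w % d:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^n_pool={d}; "
                f"pad to {-(-h // d) * d}x{-(-w // d) * d}"
            )

    def __call__(self, x, training=False, rng=None):
        """Forward pass.

        ``x``: Tensor or array (N, 1, H, W) with H, W divisible by
        ``2**n_pool``.  Returns a Tensor (N, n_classes, H, W) of softmax
        probabilities.
        """
        x = ag.astensor(x)
        self.check_input(*x.data.shape[2:])
        if training and self.cfg.bottleneck_dropout > 0 and rng is None:
            raise ValueError("training forward pass with dropout needs an rng")

        skips = []
        for L, block in enumerate(self.enc_blocks):
            x = block(x, training)
            if self.enc_scse is not None:
                x = self.enc_scse[L](x)
            skips.append(x)
            x = ag.maxpool2x2(x)

        x = self.bottleneck(x, training)
        if self.bott_scse is not None:
            x = self.bott_scse(x)
        x = ag.dropout(x, self.cfg.bottleneck_dropout, rng, training)

        for i, (up, block) in enumerate(zip(self.up_convs, self.dec_blocks)):
            if self.cfg.upsample == "transpose":
                x = up(x)
            else:
                x = up(_nearest_upsample2(x))
            x = ag.concat([skips[-(i + 1)], x], axis=1)
            x = block(x, training)
            if self.dec_scse is not None:
                x = self.dec_scse[i](x)

        return ag.softmax(self.head(x), axis=1)

    def predict_proba(self, images):
        """Inference on a batch of 2-D images (list or array, values in
        [0, 1]); returns (N, n_classes, H, W) float32 probabilities."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        with ag.no_grad():
            out = self(Tensor(x[:, None]), training=False)
        return out.data

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))


def build_network(cfg: NetConfig, seed: int = 0) -> SegNet:
    """Instantiate the network family member described by ``cfg``."""
    return SegNet(cfg, seed=seed)


def _nearest_upsample2(x):
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        n, c, h, w = x.data.shape
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(data, parents=(x,), backward=bwd)
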