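"""CNN backbone architectures for spectrogram-image screening.

Three backbones share one head design (global average pooling, dropout, a
single-unit dense layer whose sigmoid output is P(pass)):

* ``tinycnn`` — a small from-scratch 3-block CNN with aggressive input
  downsampling, fast enough to train on one CPU; the default for tests and
  synthetic experiments.
* ``densenet121`` — the DenseNet-121 topology (growth 32, blocks 6/12/24/16,
  bottleneck factor 4). Fine-tuning freezes everything up to and including
  the third transition; the last dense block, final norm and head train.
* ``convnext_tiny`` — the ConvNeXt-Tiny topology (depths 3/3/9/3, dims
  96/192/384/768, 7x7 depthwise convs, layer scale). Fine-tuning freezes the
  stem and stages 1-3; the stage-4 downsampler, stage-4 blocks and head
  train.

Both large topologies are randomly initialized (He); no pretrained weights
are bundled.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    AvgPool2d, BatchNorm2d, Conv2d, Dense, DepthwiseConv2d, Dropout, GELU,
    GlobalAvgPool, Layer, LayerNormChannels, LayerScale, MaxPool2d,
    ReLU, Sequential,
)

BACKBONES = ("densenet121", "convnext_tiny", "tinycnn")


# --- DenseNet pieces ---------------------------------------------------------

class _DenseLayer(Layer):
    """BN-ReLU-1x1(bottleneck)-BN-ReLU-3x3(growth); output is concatenated."""

    def __init__(self, c_in: int, growth: int, bn_size: int, rng):
        self.inner = Sequential([
            BatchNorm2d(c_in), ReLU(),
            Conv2d(c_in, bn_size * growth, 1, rng, bias=False),
            BatchNorm2d(bn_size * growth), ReLU(),
            Conv2d(bn_size * growth, growth, 3, rng, padding=1, bias=False),
        ])

    def params(self):
        return self.inner.params()

    def forward(self, x, train=False, rng=None):
        return self.inner.forward(x, train=train, rng=rng)

    def backward(self, dy):
        return self.inner.backward(dy)


class DenseBlock(Layer):
    """Dense connectivity: each layer sees the concat of all previous maps."""

    def __init__(self, c_in: int, n_layers: int, growth: int, rng, bn_size: int = 4):
        self.layers = [_DenseLayer(c_in + i * growth, growth, bn_size, rng)
                       for i in range(n_layers)]
        self.c_in = c_in
        self.growth = growth
        self.c_out = c_in + n_layers * growth

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        features = x
        self._widths = [features.shape[1]]
        for layer in self.layers:
            new = layer.forward(features, train=train, rng=rng)
            features = np.concatenate([features, new], axis=1)
            self._widths.append(features.shape[1])
        return features

    def backward(self, dy):
        grad = dy
        for layer, w_before in zip(reversed(self.layers), reversed(self._widths[:-1])):
            grad_prev, grad_new = grad[:, :w_before], grad[:, w_before:]
            grad = np.ascontiguousarray(grad_prev) + layer.backward(np.ascontiguousarray(grad_new))
        return grad


def _transition(c_in: int, c_out: int, rng) -> Sequential:
    return Sequential([
        BatchNorm2d(c_in), ReLU(),
        Conv2d(c_in, c_out, 1, rng, bias=False),
        AvgPool2d(2),
    ], name="transition")


# --- ConvNeXt pieces ---------------------------------------------------------

class ConvNeXtBlock(Layer):
    """dwconv7x7 -> LN -> 1x1 expand -> GELU -> 1x1 project -> scale, residual."""

    def __init__(self, dim: int, rng, ls_init: float = 1e-6):
        self.branch = Sequential([
            DepthwiseConv2d(dim, 7, rng, padding=3),
            LayerNormChannels(dim),
            Conv2d(dim, 4 * dim, 1, rng),
            GELU(),
            Conv2d(4 * dim, dim, 1, rng),
            LayerScale(dim, ls_init),
        ])

    def params(self):
        return self.branch.params()

    def forward(self, x, train=False, rng=None):
        return x + self.branch.forward(x, train=train, rng=rng)

    def backward(self, dy):
        return dy + self.branch.backward(dy)


# --- backbone builders -------------------------------------------------------

def _head(feature_dim: int, dropout_rate: float, rng) -> list[Layer]:
    return [GlobalAvgPool(), Dropout(dropout_rate), Dense(feature_dim, 1, rng)]


def build_tinycnn(dropout_rate: float, rng) -> tuple[Sequential, list[Layer]]:
    """3-block CNN on an 8x-downsampled input; returns (network, frozen_layers)."""
    layers: list[Layer] = [
        AvgPool2d(8),
        Conv2d(3, 8, 3, rng, padding=1), ReLU(), MaxPool2d(2, 2),
        Conv2d(8, 16, 3, rng, padding=1), ReLU(), MaxPool2d(2, 2),
        Conv2d(16, 32, 3, rng, padding=1), ReLU(),
    ]
    layers += _head(32, dropout_rate, rng)
    return Sequential(layers, name="tinycnn"), []


def build_densenet121(dropout_rate: float, rng) -> tuple[Sequential, list[Layer]]:
    growth, bn_size = 32, 4
    stem = [
        Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False),
        BatchNorm2d(64), ReLU(),
        MaxPool2d(3, 2, padding=1),
    ]
    block1 = DenseBlock(64, 6, growth, rng, bn_size)          # -> 256
    trans1 = _transition(block1.c_out, block1.c_out // 2, rng)  # -> 128
    block2 = DenseBlock(128, 12, growth, rng, bn_size)        # -> 512
    trans2 = _transition(block2.c_out, block2.c_out // 2, rng)  # -> 256
    block3 = DenseBlock(256, 24, growth, rng, bn_size)        # -> 1024
    trans3 = _transition(block3.c_out, block3.c_out // 2, rng)  # -> 512
    block4 = DenseBlock(512, 16, growth, rng, bn_size)        # -> 1024
    final_norm: list[Layer] = [BatchNorm2d(block4.c_out), ReLU()]
    layers = stem + [block1, trans1, block2, trans2, block3, trans3, block4] + \
        final_norm + _head(block4.c_out, dropout_rate, rng)
    frozen = stem + [block1, trans1, block2, trans2, block3, trans3]
    return Sequential(layers, name="densenet121"), frozen


def build_convnext_tiny(dropout_rate: float, rng) -> tuple[Sequential, list[Layer]]:
    depths = (3, 3, 9, 3)
    dims = (96, 192, 384, 768)
    stem: list[Layer] = [Conv2d(3, dims[0], 4, rng, stride=4), LayerNormChannels(dims[0])]
    stages: list[list[Layer]] = []
    downsamplers: list[list[Layer]] = []
    for i, (depth, dim) in enumerate(zip(depths, dims)):
        if i > 0:
            downsamplers.append([LayerNormChannels(dims[i - 1]),
                                 Conv2d(dims[i - 1], dim, 2, rng, stride=2)])
        stages.append([ConvNeXtBlock(dim, rng) for _ in range(depth)])
    layers: list[Layer] = list(stem)
    for i in range(4):
        if i > 0:
            layers += downsamplers[i - 1]
        layers += stages[i]
    layers += [GlobalAvgPool(), LayerNormChannels(dims[-1]),
               Dropout(dropout_rate), Dense(dims[-1], 1, rng)]
    # frozen: stem, stages 1-3 and the downsamplers feeding them; the
    # stage-4 downsampler and stage-4 blocks are fine-tuned.
    frozen = stem + stages[0] + downsamplers[0] + stages[1] + downsamplers[1] + stages[2]
    return Sequential(layers, name="convnext_tiny"), frozen


def build_backbone(name: str, dropout_rate: float, seed: int) -> tuple[Sequential, list[Layer]]:
    """Build a named backbone with its head; returns (network, frozen_layers).

    ``frozen_layers`` are the layers below the fine-tuning boundary; the
    caller decides whether to freeze them (transfer-learning policy) or
    train end to end.
    """
    rng = np.random.default_rng(seed)
    if name == "tinycnn":
        return build_tinycnn(dropout_rate, rng)
    if name == "densenet121":
        return build_densenet121(dropout_rate, rng)
    if name == "convnext_tiny":
        return build_convnext_tiny(dropout_rate, rng)
    raise ValueError(f"unknown backbone {name!r}; expected one of {BACKBONES}")
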