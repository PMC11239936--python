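"""Declarative layer specs and trainable-parameter accounting for the three
modified backbone networks.

The ensemble's base classifiers are structurally modified standards:

* **AlexNet (optimized)** — the single-stream five-conv trunk
  (64/192/384/256/256 filters, kernels 11/5/3/3/3) with the two hidden
  fully connected layers removed, leaving one 9216 -> K head.  At K = 4
  this totals 2,506,564 trainable parameters (2.5M).
* **VGG11_bn (optimized)** — the eight-conv batch-normalized trunk with
  the dense head replaced by global average pooling and a single
  512 -> K linear layer.
* **SE-ResNeXt-50 (32x4d)** — ResNeXt-50 with a squeeze-and-excitation
  block (reduction 16) appended to every residual unit, GELU activations,
  and a 2048 -> K head.

Only arithmetic is performed here: conv = out*(in*kh*kw/groups) + out*bias,
batchnorm = 2*C (affine scale and shift; running statistics are not
trainable), linear = out*(in+1) with bias, SE block = two bias-ful linear
maps through the C/r bottleneck.  Pooling and activations carry no weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import pandas as pd

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "SEBlock",
    "Pool",
    "Activation",
    "ArchitectureSpec",
    "layer_param_count",
    "param_count",
    "modified_alexnet_spec",
    "modified_vgg11bn_spec",
    "se_resnext50_spec",
    "ARCH_BUILDERS",
]


@dataclass(frozen=True)
class Conv2d:
    in_channels: int
    out_channels: int
    kernel: tuple[int, int]
    groups: int = 1
    bias: bool = True

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, *self.kernel) < 1:
            raise ValueError(f"non-positive conv geometry: {self}")
        if self.groups < 1 or self.in_channels % self.groups:
            raise ValueError(
                f"groups={self.groups} must divide in_channels={self.in_channels}"
            )


@dataclass(frozen=True)
class BatchNorm2d:
    channels: int

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError(f"non-positive channel count: {self}")


@dataclass(frozen=True)
class Linear:
    in_features: int
    out_features: int
    bias: bool = True

    def __post_init__(self):
        if min(self.in_features, self.out_features) < 1:
            raise ValueError(f"non-positive linear geometry: {self}")


@dataclass(frozen=True)
class SEBlock:
    channels: int
    reduction: int = 16

    def __post_init__(self):
        if self.channels < 1 or self.reduction < 1 or self.channels % self.reduction:
            raise ValueError(
                f"reduction {self.reduction} must divide channels {self.channels}"
            )


@dataclass(frozen=True)
class Pool:
    kind: str = "max"  # max | avg | adaptive_avg; no trainable weights


@dataclass(frozen=True)
class Activation:
    name: str = "relu"  # relu | gelu | softmax; no trainable weights


Layer = Union[Conv2d, BatchNorm2d, Linear, SEBlock, Pool, Activation]


@dataclass
class ArchitectureSpec:
    name: str
    layers: list = field(default_factory=list)
    num_classes: int = 1

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError(f"num_classes must be >= 1, got {self.num_classes}")


def layer_param_count(layer: Layer) -> int:
    """Trainable parameters of a single layer descriptor."""
    if isinstance(layer, Conv2d):
        kh, kw = layer.kernel
        weights = layer.out_channels * (layer.in_channels // layer.groups) * kh * kw
        return weights + (layer.out_channels if layer.bias else 0)
    if isinstance(layer, BatchNorm2d):
        return 2 * layer.channels
    if isinstance(layer, Linear):
        return layer.out_features * (layer.in_features + (1 if layer.bias else 0))
    if isinstance(layer, SEBlock):
        hidden = layer.channels // layer.reduction
        return (layer.channels * hidden + hidden) + (hidden * layer.channels + layer.channels)
    if isinstance(layer, (Pool, Activation)):
        return 0
    raise TypeError(f"unknown layer type {type(layer).__name__}")


def param_count(spec: Union[ArchitectureSpec, Sequence[Layer]]) -> int:
    """Sum of trainable parameters over the layers of a spec."""
    layers = spec.layers if isinstance(spec, ArchitectureSpec) else list(spec)
    return int(sum(layer_param_count(layer) for layer in layers))


def param_table(spec: ArchitectureSpec) -> pd.DataFrame:
    """Per-layer parameter breakdown as a DataFrame (CSV-friendly)."""
    rows = [
        {
            "index": i,
            "layer": type(layer).__name__,
            "detail": repr(layer),
            "params": layer_param_count(layer),
        }
        for i, layer in enumerate(spec.layers)
    ]
    return pd.DataFrame(rows, columns=["index", "layer", "detail", "params"])


def modified_alexnet_spec(num_classes: int = 4) -> ArchitectureSpec:
    """Single-stream AlexNet trunk with one fully connected head.

    Conv trunk 3->64 (11x11), 64->192 (5x5), then 3x3 convs 192->384,
    384->256, 256->256, all with bias; adaptive 6x6 average pool; a single
    linear 256*6*6 = 9216 -> num_classes head (the two hidden dense layers
    of the original are removed).
    """
    layers: list[Layer] = [
        Conv2d(3, 64, (11, 11)),
        Activation("relu"),
        Pool("max"),
        Conv2d(64, 192, (5, 5)),
        Activation("relu"),
        Pool("max"),
        Conv2d(192, 384, (3, 3)),
        Activation("relu"),
        Conv2d(384, 256, (3, 3)),
        Activation("relu"),
        Conv2d(256, 256, (3, 3)),
        Activation("relu"),
        Pool("max"),
        Pool("adaptive_avg"),  # to 6x6
        Linear(256 * 6 * 6, num_classes),
    ]
    return ArchitectureSpec("alexnet_opt", layers, num_classes)


_VGG11_PLAN = [64, "M", 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"]


def modified_vgg11bn_spec(num_classes: int = 4) -> ArchitectureSpec:
    """VGG11_bn conv trunk with a global-average-pooling head.

    Eight 3x3 convs (with bias, matching common pre-trained weights) each
    followed by batch norm; the dense head is replaced by GAP plus one
    linear 512 -> num_classes layer.
    """
    layers: list[Layer] = []
    in_ch = 3
    for item in _VGG11_PLAN:
        if item == "M":
            layers.append(Pool("max"))
        else:
            layers.append(Conv2d(in_ch, int(item), (3, 3)))
            layers.append(BatchNorm2d(int(item)))
            layers.append(Activation("relu"))
            in_ch = int(item)
    layers.append(Pool("adaptive_avg"))  # GAP to 1x1: no weights
    layers.append(Linear(512, num_classes))
    layers.append(Activation("softmax"))
    return ArchitectureSpec("vgg11bn_opt", layers, num_classes)


def _resnext_block(
    in_ch: int, width: int, out_ch: int, groups: int, downsample: bool, r: int
) -> list:
    layers: list[Layer] = [
        Conv2d(in_ch, width, (1, 1), bias=False),
        BatchNorm2d(width),
        Activation("gelu"),
        Conv2d(width, width, (3, 3), groups=groups, bias=False),
        BatchNorm2d(width),
        Activation("gelu"),
        Conv2d(width, out_ch, (1, 1), bias=False),
        BatchNorm2d(out_ch),
        SEBlock(out_ch, r),
    ]
    if downsample:
        layers += [Conv2d(in_ch, out_ch, (1, 1), bias=False), BatchNorm2d(out_ch)]
    layers.append(Activation("gelu"))
    return layers


def se_resnext50_spec(
    num_classes: int = 4, reduction: int = 16
) -> ArchitectureSpec:
    """SE-ResNeXt-50 (32x4d): an SE block per residual unit, GELU, K-class head.

    Standard layout: 7x7 stem, four stages of [3, 4, 6, 3] grouped
    bottleneck units (cardinality 32), output widths 256/512/1024/2048,
    projection shortcut at each stage entry, then GAP and a 2048 -> K
    linear head.
    """
    layers: list[Layer] = [
        Conv2d(3, 64, (7, 7), bias=False),
        BatchNorm2d(64),
        Activation("gelu"),
        Pool("max"),
    ]
    in_ch = 64
    stage_cfg = [  # (width, out_channels, n_blocks)
        (128, 256, 3),
        (256, 512, 4),
        (512, 1024, 6),
        (1024, 2048, 3),
    ]
    for width, out_ch, n_blocks in stage_cfg:
        for b in range(n_blocks):
            layers += _resnext_block(
                in_ch, width, out_ch, groups=32, downsample=(b == 0), r=reduction
            )
            in_ch = out_ch
    layers.append(Pool("adaptive_avg"))
    layers.append(Linear(2048, num_classes))
    return ArchitectureSpec("se_resnext50", layers, num_classes)


ARCH_BUILDERS = {
    "alexnet_opt": modified_alexnet_spec,
    "vgg11bn_opt": modified_vgg11bn_spec,
    "se_resnext50": se_resnext50_spec,
}
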