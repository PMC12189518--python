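"""Convolutional backbone trunks used as frozen feature extractors.

Each builder reproduces the published architecture of its namesake network
with the classification top removed, so parameter counts match the reference
implementations exactly (EfficientNet-B0: 4,049,571; ResNet50: 23,587,712;
Inception-v3: 21,802,784 — batch-norm moving statistics included). The trunks
end just before global pooling; the classification head is appended in
:mod:`cdml_eeg.classifier`.

Backbones are fully convolutional, so any input height/width that survives the
stride pyramid is accepted — in particular the 250x250 time-frequency tensors
used throughout this package.
"""

from __future__ import annotations

import numpy as np

from ._nn import (
    Activation, AvgPool2D, BatchNorm, Conv2D, DepthwiseConv2D, Layer,
    MaxPool2D, Parallel, Residual, Sequential, relu, swish,
)

__all__ = ["build_backbone", "BACKBONE_FEATURES", "BACKBONES"]

#: feature-map depth each trunk presents to global average pooling
BACKBONE_FEATURES = {
    "efficientnet-b0": 1280,
    "resnet50": 2048,
    "inception-v3": 2048,
}

BACKBONES = tuple(BACKBONE_FEATURES)


# ---------------------------------------------------------------- EfficientNet

# (kernel, repeats, filters_in, filters_out, expand_ratio, stride)
_EFFNET_B0_BLOCKS = [
    (3, 1, 32, 16, 1, 1),
    (3, 2, 16, 24, 6, 2),
    (5, 2, 24, 40, 6, 2),
    (3, 3, 40, 80, 6, 2),
    (5, 3, 80, 112, 6, 1),
    (5, 4, 112, 192, 6, 2),
    (3, 1, 192, 320, 6, 1),
]


def _mbconv(cin: int, cout: int, kernel: int, stride: int, expand: int,
            rng: np.random.Generator, name: str) -> Layer:
    """Mobile inverted bottleneck block with squeeze-excitation (ratio 0.25)."""
    from ._nn import SqueezeExcite

    mid = cin * expand
    seq: list[Layer] = []
    if expand != 1:
        seq += [Conv2D(cin, mid, 1, use_bias=False, rng=rng, name=f"{name}/expand"),
                BatchNorm(mid, name=f"{name}/expand_bn"), Activation(swish)]
    seq += [DepthwiseConv2D(mid, kernel, stride=stride, rng=rng, name=f"{name}/dw"),
            BatchNorm(mid, name=f"{name}/dw_bn"), Activation(swish),
            SqueezeExcite(mid, max(1, cin // 4), rng=rng, name=name),
            Conv2D(mid, cout, 1, use_bias=False, rng=rng, name=f"{name}/project"),
            BatchNorm(cout, name=f"{name}/project_bn")]
    body = Sequential(seq, name=name)
    if stride == 1 and cin == cout:
        return Residual(body)
    return body


class InputNorm(Layer):
    """Per-channel standardisation by the pretraining corpus statistics.

    Holds the channel means and variances of the natural-image corpus the
    backbone was trained on (plus the sample-count scalar those statistics
    were accumulated over, kept for checkpoint compatibility). With
    ``active=False`` the layer is the identity — appropriate for randomly
    initialised trunks where corpus statistics have no meaning.
    """

    #: ImageNet channel statistics on the [0, 1] scale
    IMAGENET_MEAN = (0.485, 0.456, 0.406)
    IMAGENET_STD = (0.229, 0.224, 0.225)

    def __init__(self, active: bool = False, name: str = "input_norm"):
        self.name = name
        self.active = active
        self.mean = np.asarray(self.IMAGENET_MEAN, dtype=np.float32)
        self.variance = np.asarray(self.IMAGENET_STD, dtype=np.float32) ** 2
        self.count = np.zeros(1, dtype=np.float32)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if not self.active:
            return x
        return (x - self.mean) / np.sqrt(self.variance)


def _efficientnet_b0(rng: np.random.Generator) -> Layer:
    layers: list[Layer] = [
        InputNorm(),
        Conv2D(3, 32, 3, stride=2, use_bias=False, rng=rng, name="stem"),
        BatchNorm(32, name="stem_bn"), Activation(swish),
    ]
    for bi, (k, repeats, cin, cout, expand, stride) in enumerate(_EFFNET_B0_BLOCKS):
        for r in range(repeats):
            layers.append(_mbconv(cin if r == 0 else cout, cout, k,
                                  stride if r == 0 else 1, expand, rng,
                                  name=f"block{bi + 1}{chr(ord('a') + r)}"))
    layers += [Conv2D(320, 1280, 1, use_bias=False, rng=rng, name="top"),
               BatchNorm(1280, name="top_bn"), Activation(swish)]
    return Sequential(layers, name="efficientnet-b0")


# -------------------------------------------------------------------- ResNet50

def _conv_bn(cin: int, cout: int, kernel, stride, rng, name,
             padding: str = "same") -> Sequential:
    return Sequential([
        Conv2D(cin, cout, kernel, stride=stride, padding=padding, use_bias=True,
               rng=rng, name=name),
        BatchNorm(cout, name=f"{name}_bn"),
    ])


def _bottleneck(cin: int, filters: tuple[int, int, int], stride: int,
                project: bool, rng: np.random.Generator, name: str) -> Layer:
    f1, f2, f3 = filters
    main = Sequential([
        _conv_bn(cin, f1, 1, stride, rng, f"{name}/a"), Activation(relu),
        _conv_bn(f1, f2, 3, 1, rng, f"{name}/b"), Activation(relu),
        _conv_bn(f2, f3, 1, 1, rng, f"{name}/c"),
    ])
    shortcut = _conv_bn(cin, f3, 1, stride, rng, f"{name}/sc") if project else None
    return Residual(main, shortcut, activation=relu, name=name)


def _resnet50(rng: np.random.Generator) -> Layer:
    layers: list[Layer] = [
        _conv_bn(3, 64, 7, 2, rng, "conv1"), Activation(relu),
        MaxPool2D(3, 2, padding="same"),
    ]
    cin = 64
    stage_cfg = [((64, 64, 256), 3, 1), ((128, 128, 512), 4, 2),
                 ((256, 256, 1024), 6, 2), ((512, 512, 2048), 3, 2)]
    for si, (filters, blocks, stride) in enumerate(stage_cfg, start=2):
        for b in range(blocks):
            layers.append(_bottleneck(cin, filters, stride if b == 0 else 1,
                                      project=(b == 0), rng=rng,
                                      name=f"conv{si}_block{b + 1}"))
            cin = filters[2]
    return Sequential(layers, name="resnet50")


# ---------------------------------------------------------------- Inception-v3

def _cbr(cin: int, cout: int, kernel, rng, name, stride: int = 1,
         padding: str = "same") -> Sequential:
    """Conv (no bias) + BN (no gamma) + ReLU, the Inception-v3 unit."""
    return Sequential([
        Conv2D(cin, cout, kernel, stride=stride, padding=padding, use_bias=False,
               rng=rng, name=name),
        BatchNorm(cout, scale=False, name=f"{name}_bn"),
        Activation(relu),
    ])


def _inception_v3(rng: np.random.Generator) -> Layer:  # noqa: C901
    g = rng
    layers: list[Layer] = [
        _cbr(3, 32, 3, g, "c1", stride=2, padding="valid"),
        _cbr(32, 32, 3, g, "c2", padding="valid"),
        _cbr(32, 64, 3, g, "c3"),
        MaxPool2D(3, 2),
        _cbr(64, 80, 1, g, "c4", padding="valid"),
        _cbr(80, 192, 3, g, "c5", padding="valid"),
        MaxPool2D(3, 2),
    ]

    def mixed_a(cin: int, pool: int, name: str) -> Parallel:
        return Parallel([
            _cbr(cin, 64, 1, g, f"{name}/1x1"),
            Sequential([_cbr(cin, 48, 1, g, f"{name}/5x5_1"),
                        _cbr(48, 64, 5, g, f"{name}/5x5_2")]),
            Sequential([_cbr(cin, 64, 1, g, f"{name}/3x3_1"),
                        _cbr(64, 96, 3, g, f"{name}/3x3_2"),
                        _cbr(96, 96, 3, g, f"{name}/3x3_3")]),
            Sequential([AvgPool2D(3, 1, padding="same"),
                        _cbr(cin, pool, 1, g, f"{name}/pool")]),
        ], name=name)

    layers += [mixed_a(192, 32, "mixed0"), mixed_a(256, 64, "mixed1"),
               mixed_a(288, 64, "mixed2")]

    layers.append(Parallel([
        _cbr(288, 384, 3, g, "mixed3/3x3", stride=2, padding="valid"),
        Sequential([_cbr(288, 64, 1, g, "mixed3/dbl_1"),
                    _cbr(64, 96, 3, g, "mixed3/dbl_2"),
                    _cbr(96, 96, 3, g, "mixed3/dbl_3", stride=2, padding="valid")]),
        MaxPool2D(3, 2),
    ], name="mixed3"))

    def mixed_b(mid: int, name: str) -> Parallel:
        return Parallel([
            _cbr(768, 192, 1, g, f"{name}/1x1"),
            Sequential([_cbr(768, mid, 1, g, f"{name}/7x7_1"),
                        _cbr(mid, mid, (1, 7), g, f"{name}/7x7_2"),
                        _cbr(mid, 192, (7, 1), g, f"{name}/7x7_3")]),
            Sequential([_cbr(768, mid, 1, g, f"{name}/7x7dbl_1"),
                        _cbr(mid, mid, (7, 1), g, f"{name}/7x7dbl_2"),
                        _cbr(mid, mid, (1, 7), g, f"{name}/7x7dbl_3"),
                        _cbr(mid, mid, (7, 1), g, f"{name}/7x7dbl_4"),
                        _cbr(mid, 192, (1, 7), g, f"{name}/7x7dbl_5")]),
            Sequential([AvgPool2D(3, 1, padding="same"),
                        _cbr(768, 192, 1, g, f"{name}/pool")]),
        ], name=name)

    layers += [mixed_b(128, "mixed4"), mixed_b(160, "mixed5"),
               mixed_b(160, "mixed6"), mixed_b(192, "mixed7")]

    layers.append(Parallel([
        Sequential([_cbr(768, 192, 1, g, "mixed8/3x3_1"),
                    _cbr(192, 320, 3, g, "mixed8/3x3_2", stride=2, padding="valid")]),
        Sequential([_cbr(768, 192, 1, g, "mixed8/7x7x3_1"),
                    _cbr(192, 192, (1, 7), g, "mixed8/7x7x3_2"),
                    _cbr(192, 192, (7, 1), g, "mixed8/7x7x3_3"),
                    _cbr(192, 192, 3, g, "mixed8/7x7x3_4", stride=2, padding="valid")]),
        MaxPool2D(3, 2),
    ], name="mixed8"))

    def mixed_c(cin: int, name: str) -> Parallel:
        return Parallel([
            _cbr(cin, 320, 1, g, f"{name}/1x1"),
            Sequential([_cbr(cin, 384, 1, g, f"{name}/3x3_1"),
                        Parallel([_cbr(384, 384, (1, 3), g, f"{name}/3x3_2a"),
                                  _cbr(384, 384, (3, 1), g, f"{name}/3x3_2b")])]),
            Sequential([_cbr(cin, 448, 1, g, f"{name}/dbl_1"),
                        _cbr(448, 384, 3, g, f"{name}/dbl_2"),
                        Parallel([_cbr(384, 384, (1, 3), g, f"{name}/dbl_3a"),
                                  _cbr(384, 384, (3, 1), g, f"{name}/dbl_3b")])]),
            Sequential([AvgPool2D(3, 1, padding="same"),
                        _cbr(cin, 192, 1, g, f"{name}/pool")]),
        ], name=name)

    layers += [mixed_c(1280, "mixed9"), mixed_c(2048, "mixed10")]
    return Sequential(layers, name="inception-v3")


_BUILDERS = {
    "efficientnet-b0": _efficientnet_b0,
    "resnet50": _resnet50,
    "inception-v3": _inception_v3,
}


def build_backbone(name: str, rng: np.random.Generator | None = None) -> Layer:
    """Instantiate a randomly initialised trunk by canonical name."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown backbone {name!r}; supported: {', '.join(BACKBONES)}")
    return _BUILDERS[name](rng or np.random.default_rng(0))
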