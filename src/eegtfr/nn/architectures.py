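"""Classifier architectures for 224x224 RGB time-frequency images.

Four architectures are provided, all ending in a two-way linear head
(index 0 = responder, index 1 = non-responder):

* ``resnet18`` — the 18-layer residual network (two basic blocks per
  stage, widths 64/128/256/512).
* ``mobilenet_v3`` — MobileNet-V3 Large: inverted-residual bottlenecks
  with hard-swish activations and squeeze-and-excitation attention.
* ``efficientnet_b0`` — the EfficientNet baseline of MBConv blocks with
  SiLU activations and SE attention.
* ``tinyvit_hybrid`` — the hybrid model: the ResNet-18 trunk up to its
  final convolutional stage yields a (B, 512, 7, 7) feature map that is
  flattened into 49 tokens of dimension 512, given learnable 1-D
  positional embeddings, passed through two 8-head self-attention
  encoder blocks (MLP ratio 4 -> inner width 2048, dropout 0.1),
  layer-normalised, mean-pooled over tokens and classified linearly.

A fifth, deliberately small ``tiny_cnn`` (two conv layers, 32x32 input)
exists for fast experiments and tests only; it is not part of the
evaluated architecture set.

ImageNet-pretrained weights are an external binary asset; models here
are randomly initialised unless a local weights file is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (Activation, BatchNorm2d, Conv2d, Dropout, GlobalAvgPool,
                     LayerNorm, Linear, MaxPool2d, Module, Sequential,
                     TransformerBlock)

MODEL_NAMES = ("resnet18", "mobilenet_v3", "efficientnet_b0", "tinyvit_hybrid",
               "tiny_cnn")


@dataclass
class ModelSpec:
    """Which architecture to build and how."""

    name: str = "tiny_cnn"
    pretrained: bool = False
    n_classes: int = 2
    input_size: int | None = None   # override for fully-convolutional models
    # tinyvit_hybrid structural constants
    n_tokens: int = 49
    token_dim: int = 512
    n_layers: int = 2
    n_heads: int = 8
    mlp_ratio: int = 4
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.pretrained:
            raise ValueError(
                "pretrained weights are an external asset and are not bundled; "
                "build with pretrained=False and load a local checkpoint with "
                "Module.set_state if you have one"
            )


def _cbr(rng, cin, cout, k, s, p, act="relu", groups=1):
    return Sequential(Conv2d(rng, cin, cout, k, s, p, groups=groups),
                      BatchNorm2d(cout), Activation(act))


class BasicBlock(Module):
    def __init__(self, rng, cin, cout, stride):
        self.conv1 = Conv2d(rng, cin, cout, 3, stride, 1)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(rng, cout, cout, 3, 1, 1)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = Sequential(Conv2d(rng, cin, cout, 1, stride, 0), BatchNorm2d(cout))
        else:
            self.down = None

    def forward(self, x):
        idn = x if self.down is None else self.down(x)
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + idn).relu()


class ResNet18Trunk(Module):
    """Stem + four residual stages; 224x224x3 -> (B, 512, 7, 7)."""

    out_channels = 512

    def __init__(self, rng):
        self.stem = Sequential(Conv2d(rng, 3, 64, 7, 2, 3), BatchNorm2d(64),
                               Activation("relu"), MaxPool2d(3, 2, 1))
        stages = []
        cin = 64
        for cout, stride in ((64, 1), (128, 2), (256, 2), (512, 2)):
            stages.append(BasicBlock(rng, cin, cout, stride))
            stages.append(BasicBlock(rng, cout, cout, 1))
            cin = cout
        self.stages = stages

    def forward(self, x):
        x = self.stem(x)
        for blk in self.stages:
            x = blk(x)
        return x


class ResNet18(Module):
    input_size = 224

    def __init__(self, rng, n_classes=2):
        self.trunk = ResNet18Trunk(rng)
        self.pool = GlobalAvgPool()
        self.fc = Linear(rng, 512, n_classes)

    def forward(self, x):
        return self.fc(self.pool(self.trunk(x)))


class SqueezeExcite(Module):
    def __init__(self, rng, channels, squeeze, gate="hardsigmoid"):
        self.fc1 = Conv2d(rng, channels, squeeze, 1, bias=True)
        self.fc2 = Conv2d(rng, squeeze, channels, 1, bias=True)
        self.gate = gate

    def forward(self, x):
        b, c = x.shape[0], x.shape[1]
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.fc2(self.fc1(s).relu())
        return x * getattr(s, self.gate)()


class InvertedResidual(Module):
    """MobileNet/EfficientNet bottleneck: expand -> depthwise -> SE -> project."""

    def __init__(self, rng, cin, exp, cout, kernel, stride, use_se, act,
                 se_squeeze=None, se_gate="hardsigmoid"):
        self.use_res = stride == 1 and cin == cout
        mods = []
        if exp != cin:
            mods.append(_cbr(rng, cin, exp, 1, 1, 0, act))
        mods.append(_cbr(rng, exp, exp, kernel, stride, kernel // 2, act, groups=exp))
        self.pre = Sequential(*mods)
        self.se = (SqueezeExcite(rng, exp, se_squeeze or max(1, exp // 4), se_gate)
                   if use_se else None)
        self.project = Sequential(Conv2d(rng, exp, cout, 1, 1, 0), BatchNorm2d(cout))

    def forward(self, x):
        h = self.pre(x)
        if self.se is not None:
            h = self.se(h)
        h = self.project(h)
        return h + x if self.use_res else h


# (kernel, expansion, out, SE, activation, stride)
_MOBILENET_V3_LARGE = [
    (3, 16, 16, False, "relu", 1),
    (3, 64, 24, False, "relu", 2),
    (3, 72, 24, False, "relu", 1),
    (5, 72, 40, True, "relu", 2),
    (5, 120, 40, True, "relu", 1),
    (5, 120, 40, True, "relu", 1),
    (3, 240, 80, False, "hardswish", 2),
    (3, 200, 80, False, "hardswish", 1),
    (3, 184, 80, False, "hardswish", 1),
    (3, 184, 80, False, "hardswish", 1),
    (3, 480, 112, True, "hardswish", 1),
    (3, 672, 112, True, "hardswish", 1),
    (5, 672, 160, True, "hardswish", 2),
    (5, 960, 160, True, "hardswish", 1),
    (5, 960, 160, True, "hardswish", 1),
]


class MobileNetV3Large(Module):
    input_size = 224

    def __init__(self, rng, n_classes=2):
        self.stem = _cbr(rng, 3, 16, 3, 2, 1, "hardswish")
        blocks, cin = [], 16
        for k, exp, cout, se, act, s in _MOBILENET_V3_LARGE:
            blocks.append(InvertedResidual(rng, cin, exp, cout, k, s, se, act))
            cin = cout
        self.blocks = blocks
        self.head_conv = _cbr(rng, cin, 960, 1, 1, 0, "hardswish")
        self.pool = GlobalAvgPool()
        self.fc1 = Linear(rng, 960, 1280)
        self.drop = Dropout(0.2, rng)
        self.fc2 = Linear(rng, 1280, n_classes)

    def forward(self, x):
        x = self.stem(x)
        for blk in self.blocks:
            x = blk(x)
        x = self.pool(self.head_conv(x))
        return self.fc2(self.drop(self.fc1(x).hardswish()))


# (kernel, expansion factor, out, repeats, stride)
_EFFICIENTNET_B0 = [
    (3, 1, 16, 1, 1),
    (3, 6, 24, 2, 2),
    (5, 6, 40, 2, 2),
    (3, 6, 80, 3, 2),
    (5, 6, 112, 3, 1),
    (5, 6, 192, 4, 2),
    (3, 6, 320, 1, 1),
]


class EfficientNetB0(Module):
    input_size = 224

    def __init__(self, rng, n_classes=2):
        self.stem = _cbr(rng, 3, 32, 3, 2, 1, "silu")
        blocks, cin = [], 32
        for k, t, cout, reps, stride in _EFFICIENTNET_B0:
            for r in range(reps):
                s = stride if r == 0 else 1
                blocks.append(InvertedResidual(
                    rng, cin, cin * t, cout, k, s, True, "silu",
                    se_squeeze=max(1, cin // 4), se_gate="sigmoid"))
                cin = cout
        self.blocks = blocks
        self.head_conv = _cbr(rng, cin, 1280, 1, 1, 0, "silu")
        self.pool = GlobalAvgPool()
        self.drop = Dropout(0.2, rng)
        self.fc = Linear(rng, 1280, n_classes)

    def forward(self, x):
        x = self.stem(x)
        for blk in self.blocks:
            x = blk(x)
        return self.fc(self.drop(self.pool(self.head_conv(x))))


class TinyViTHybrid(Module):
    """ResNet-18 trunk + compact Transformer encoder over 49 spatial tokens."""

    input_size = 224

    def __init__(self, rng, spec: ModelSpec):
        self.trunk = ResNet18Trunk(rng)
        self.n_tokens = spec.n_tokens
        self.token_dim = spec.token_dim
        self.pos_embed = Tensor(
            (rng.standard_normal((1, spec.n_tokens, spec.token_dim)) * 0.02
             ).astype(np.float32), requires_grad=True)
        self.encoder = [TransformerBlock(rng, spec.token_dim, spec.n_heads,
                                         spec.mlp_ratio, spec.dropout)
                        for _ in range(spec.n_layers)]
        self.norm = LayerNorm(spec.token_dim)
        self.head = Linear(rng, spec.token_dim, spec.n_classes)

    @property
    def mlp_inner_width(self):
        return self.encoder[0].mlp_inner_width

    def tokens(self, x):
        feat = self.trunk(x)                       # (B, 512, 7, 7)
        b, c = feat.shape[0], feat.shape[1]
        n = feat.shape[2] * feat.shape[3]
        if n != self.n_tokens or c != self.token_dim:
            raise ValueError(
                f"trunk produced {n} tokens of dim {c}; expected "
                f"{self.n_tokens} of dim {self.token_dim} (input must be "
                f"{self.input_size}x{self.input_size})"
            )
        return feat.reshape(b, c, n).transpose(0, 2, 1) + self.pos_embed

    def forward(self, x):
        tok = self.tokens(x)
        for blk in self.encoder:
            tok = blk(tok)
        return self.head(self.norm(tok).mean(axis=1))


class TinyCNN(Module):
    """Two conv layers + linear head; fast-test spectrogram model.

    Pooling averages over the time axis only, keeping the frequency
    axis intact — a classifier of time-frequency images must be able to
    tell *which* rows are active, which global average pooling would
    destroy.
    """

    def __init__(self, rng, n_classes=2, input_size=32):
        self.input_size = input_size
        self.body = Sequential(
            _cbr(rng, 3, 16, 3, 2, 1),
            _cbr(rng, 16, 32, 3, 2, 1),
        )
        n_freq_rows = input_size // 4   # two stride-2 convs
        self.fc = Linear(rng, 32 * n_freq_rows, n_classes)

    def forward(self, x):
        feat = self.body(x).mean(axis=3)          # (B, C, freq_rows)
        b, c, h = feat.shape
        return self.fc(feat.reshape(b, c * h))


def build_model(spec: ModelSpec) -> Module:
    """Construct a randomly initialised classifier from its spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.name == "resnet18":
        model = ResNet18(rng, spec.n_classes)
    elif spec.name == "mobilenet_v3":
        model = MobileNetV3Large(rng, spec.n_classes)
    elif spec.name == "efficientnet_b0":
        model = EfficientNetB0(rng, spec.n_classes)
    elif spec.name == "tinyvit_hybrid":
        model = TinyViTHybrid(rng, spec)
    else:
        return TinyCNN(rng, spec.n_classes, input_size=spec.input_size or 32)
    if spec.input_size is not None:
        raise ValueError(
            "input_size can only be overridden for tiny_cnn; the evaluated "
            f"architectures expect {model.input_size}x{model.input_size} input"
        )
    return model
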