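"""Declarative layer specifications for the two generator/discriminator pairs.

The reconstruction framework is a cascade of two conditional GANs: Module 1
translates a sinogram into a coarse image with a U-Net generator and a
patch-based discriminator; Module 2 refines that image with a
style-embedding generator (convolutional encoder, residual bottleneck,
adaptive-instance-normalisation blocks fed by a latent mapping network, and
a transposed-convolution decoder).  The builders below emit
:class:`NetworkSpec` objects — a declarative layer list that the runnable
networks in :mod:`modgan.nn.networks` instantiate — so the architecture can
be inspected, shape-checked and serialised independently of any weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "LatentVector",
    "build_module1_generator",
    "build_patch_discriminator",
    "build_module2_generator",
    "receptive_field",
    "propagate_shapes",
    "LATENT_DIM",
    "MODULE1_ENCODER_FILTERS",
]

LATENT_DIM = 1024
#: encoder filter progression of the Module-1 U-Net at full (256 px) scale
MODULE1_ENCODER_FILTERS = (64, 128, 256, 512, 512, 512, 512, 512)

Kind = Literal["conv", "transpose_conv", "fully_connected", "residual_block", "adain_block"]


@dataclass(frozen=True)
class LayerSpec:
    kind: Kind
    filters: int
    kernel: int = 4
    stride: int = 1
    normalization: Literal["instance", "adaptive_instance", "none"] = "none"
    activation: Literal["leaky_relu", "relu", "tanh", "none"] = "none"
    dropout: float = 0.0

    def __post_init__(self):
        if self.filters < 1 or self.kernel < 1 or self.stride < 1:
            raise ValueError("filters, kernel and stride must all be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class NetworkSpec:
    name: str
    input_shape: tuple[int, int, int]  # (H, W, C)
    layers: list[LayerSpec]
    skip_connections: list[tuple[int, int]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        raw = yaml.safe_load(text)
        raw["layers"] = [LayerSpec(**d) for d in raw["layers"]]
        raw["input_shape"] = tuple(raw["input_shape"])
        raw["skip_connections"] = [tuple(p) for p in raw.get("skip_connections", [])]
        return cls(**raw)


@dataclass
class LatentVector:
    """Latent noise vector for the style mapping network (default dim 1024)."""

    values: "object"
    dimension: int = LATENT_DIM

    def __post_init__(self):
        import numpy as np

        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.values.size != self.dimension:
            raise ValueError(
                f"latent vector has {self.values.size} entries, declared {self.dimension}"
            )


def _scaled(filters: int, width: float) -> int:
    return max(1, int(round(filters * width)))


def _depth_for(image_size: int) -> int:
    depth = int(round(math.log2(image_size)))
    if 2**depth != image_size or depth < 3:
        raise ValueError("image size must be a power of two >= 8")
    return depth


def module1_filters(image_size: int = 256, width: float = 1.0) -> list[int]:
    """Encoder filters for an image size: the 256-px progression has eight
    layers (64, 128, 256, 512 x5); smaller inputs truncate the tail so the
    bottleneck still reaches 1 x 1."""
    depth = _depth_for(image_size)
    base = list(MODULE1_ENCODER_FILTERS)
    if depth <= len(base):
        prog = base[:depth]
    else:  # deeper than 256 px: repeat the widest layer
        prog = base + [base[-1]] * (depth - len(base))
    return [_scaled(f, width) for f in prog]


def build_module1_generator(image_size: int = 256, in_channels: int = 3,
                            out_channels: int = 3, width: float = 1.0) -> NetworkSpec:
    """U-Net sinogram-to-image generator.

    Encoder: stride-2 4x4 convolutions with instance norm + leaky-ReLU
    (no normalisation on the first layer; the bottleneck uses plain ReLU).
    Decoder: transposed convolutions with the filter counts reversed, skip
    connections pairing equal-resolution encoder/decoder stages, and a tanh
    output layer so the image lands in [-1, 1].
    """
    enc_filters = module1_filters(image_size, width)
    depth = len(enc_filters)
    layers: list[LayerSpec] = []
    for i, f in enumerate(enc_filters):
        if i == 0:
            layers.append(LayerSpec("conv", f, 4, 2, "none", "leaky_relu"))
        elif i == depth - 1:  # bottleneck
            layers.append(LayerSpec("conv", f, 4, 2, "none", "relu"))
        else:
            layers.append(LayerSpec("conv", f, 4, 2, "instance", "leaky_relu"))
    for j in range(depth):
        if j == depth - 1:
            layers.append(LayerSpec("transpose_conv", out_channels, 4, 2, "none", "tanh"))
        else:
            layers.append(
                LayerSpec("transpose_conv", enc_filters[depth - 2 - j], 4, 2,
                          "instance", "relu")
            )
    skips = [(i, 2 * depth - 1 - i) for i in range(depth - 1)]
    return NetworkSpec(
        name="module1_generator",
        input_shape=(image_size, image_size, in_channels),
        layers=layers,
        skip_connections=skips,
        extras={"image_size": image_size, "width": width,
                "encoder_filters": enc_filters},
    )


def build_patch_discriminator(filters: list[int] | None = None,
                              image_size: int = 256,
                              in_channels: int = 6,
                              width: float = 1.0) -> NetworkSpec:
    """Patch discriminator: hidden 4x4 stride-2 convolutions (instance norm +
    leaky-ReLU) followed by a single-filter 1x1 stride-1 output layer.  The
    input is the channel-concatenated (condition, image) pair, hence six
    channels by default.  With the default two hidden layers the theoretical
    receptive field of one output unit is 10 input pixels."""
    if filters is None:
        filters = [64, 128]
    if not filters:
        raise ValueError("discriminator needs at least one hidden conv layer")
    layers = [
        LayerSpec("conv", _scaled(f, width), 4, 2, "instance", "leaky_relu")
        for f in filters
    ]
    layers.append(LayerSpec("conv", 1, 1, 1, "none", "none"))
    return NetworkSpec(
        name="patch_discriminator",
        input_shape=(image_size, image_size, in_channels),
        layers=layers,
        extras={"hidden_layers": len(filters), "width": width},
    )


def build_module2_generator(image_size: int = 256, in_channels: int = 3,
                            out_channels: int = 3, width: float = 1.0,
                            n_adain_blocks: int = 2,
                            dropout: float = 0.5) -> NetworkSpec:
    """Style-embedding enhancement generator.

    Convolutional encoder (64 filters at stride 1, then 128/256/512/512 at
    stride 2) -> three residual blocks of two 512-filter convolutions ->
    residual join (pre-block features concatenated with the second block's
    output, projected back to 512 channels by a 1x1 convolution) -> AdaIN
    blocks whose per-channel scale/shift come from the latent mapping
    network -> transposed-convolution decoder (512, 256, 128, 64; dropout on
    the first three) -> 3-filter stride-1 output convolution with tanh.
    """
    c = [_scaled(f, width) for f in (64, 128, 256, 512, 512)]
    base = c[-1]
    layers: list[LayerSpec] = [LayerSpec("conv", c[0], 4, 1, "instance", "relu")]
    for f in c[1:]:
        layers.append(LayerSpec("conv", f, 4, 2, "instance", "relu"))
    for _ in range(3):
        layers.append(LayerSpec("residual_block", base, 4, 1, "instance", "relu"))
    layers.append(LayerSpec("conv", base, 1, 1, "none", "none"))  # residual join projection
    for _ in range(n_adain_blocks):
        layers.append(LayerSpec("adain_block", base, 4, 1, "adaptive_instance", "relu"))
    for f, drop in zip([_scaled(x, width) for x in (512, 256, 128, 64)],
                       (dropout, dropout, dropout, 0.0)):
        layers.append(LayerSpec("transpose_conv", f, 4, 2, "instance", "relu", drop))
    layers.append(LayerSpec("conv", out_channels, 4, 1, "none", "tanh"))
    return NetworkSpec(
        name="module2_generator",
        input_shape=(image_size, image_size, in_channels),
        layers=layers,
        extras={
            "image_size": image_size,
            "width": width,
            "n_adain_blocks": n_adain_blocks,
            "fc_block": {"n_layers": 3, "width": base, "latent_dim": LATENT_DIM},
        },
    )


def receptive_field(spec: NetworkSpec) -> int:
    """Theoretical receptive field (in input pixels) of one output unit.

    Recursive formula over a pure convolution stack: starting from r = 1,
    j = 1, each layer updates r <- r + (k - 1) * j and j <- j * stride.
    """
    r, j = 1, 1
    for layer in spec.layers:
        if layer.kind != "conv":
            raise ValueError(
                f"receptive_field supports conv-only specs; found {layer.kind!r}"
            )
        r += (layer.kernel - 1) * j
        j *= layer.stride
    return r


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def propagate_shapes(spec: NetworkSpec) -> list[tuple[int, int, int]]:
    """Propagate (H, W, C) through the layer list, honouring skip concats.

    Raises ``ValueError`` on an impossible spec (spatial collapse below 1,
    or a skip endpoint out of range).
    """
    h, w, cin = spec.input_shape
    incoming: dict[int, list[int]] = {}
    for src, dst in spec.skip_connections:
        if not (0 <= src < len(spec.layers)) or not (0 <= dst < len(spec.layers)):
            raise ValueError(f"skip endpoint ({src}, {dst}) out of range")
        if dst <= src:
            raise ValueError("skip connections must run forward")
        incoming.setdefault(dst, []).append(src)
    shapes: list[tuple[int, int, int]] = []
    for idx, layer in enumerate(spec.layers):
        for src in incoming.get(idx, []):
            cin += shapes[src][2]
        if layer.kind in ("conv",):
            h, w = _ceil_div(h, layer.stride), _ceil_div(w, layer.stride)
            cin = layer.filters
        elif layer.kind == "transpose_conv":
            h, w = h * layer.stride, w * layer.stride
            cin = layer.filters
        elif layer.kind in ("residual_block", "adain_block"):
            if cin != layer.filters:
                raise ValueError(
                    f"{layer.kind} at index {idx} expects {layer.filters} channels, got {cin}"
                )
        elif layer.kind == "fully_connected":
            h = w = 1
            cin = layer.filters
        if h < 1 or w < 1:
            raise ValueError(f"spatial size collapsed below 1 at layer {idx}")
        shapes.append((h, w, cin))
    return shapes
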