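"""Runnable generators and discriminators built from the declarative specs."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concat, conv2d
from .layers import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Linear,
    Module,
    Parameter,
    adain,
    instance_norm_1d,
    instance_norm_2d,
)
from .specs import (
    LATENT_DIM,
    NetworkSpec,
    build_module1_generator,
    build_module2_generator,
    build_patch_discriminator,
    module1_filters,
)

__all__ = [
    "UNetGenerator",
    "PatchDiscriminator",
    "MappingNetwork",
    "StyleEnhancer",
    "receptive_field_footprint",
]


class UNetGenerator(Module):
    """Module-1 generator: U-Net mapping a sinogram tensor to a coarse image.

    ``width`` scales every filter count, letting the identical architecture
    run at desk scale (e.g. width=0.125 at 64 px) or at the full 256-px
    configuration (width=1).
    """

    def __init__(self, image_size: int = 256, in_channels: int = 3,
                 out_channels: int = 3, width: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        filters = module1_filters(image_size, width)
        self.image_size = image_size
        self.depth = len(filters)
        self.enc = [
            Conv2d(in_channels if i == 0 else filters[i - 1], f, 4, 2, rng=rng)
            for i, f in enumerate(filters)
        ]
        dec_out = [filters[self.depth - 2 - j] for j in range(self.depth - 1)] + [out_channels]
        self.dec = []
        for j, f in enumerate(dec_out):
            cin = filters[-1] if j == 0 else dec_out[j - 1] + filters[self.depth - 1 - j]
            self.dec.append(ConvTranspose2d(cin, f, 4, 2, rng=rng))
        self._spec = build_module1_generator(image_size, in_channels, out_channels, width)

    def spec(self) -> NetworkSpec:
        return self._spec

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        skips: list[Tensor] = []
        for i, layer in enumerate(self.enc):
            x = layer(x)
            if i == 0:
                x = x.leaky_relu(0.2)
            elif i == self.depth - 1:
                x = x.relu()
            else:
                x = instance_norm_2d(x).leaky_relu(0.2)
            if i < self.depth - 1:
                skips.append(x)
        for j, layer in enumerate(self.dec):
            if j > 0:
                x = concat([x, skips[self.depth - 1 - j]], axis=1)
            x = layer(x)
            if j == self.depth - 1:
                x = x.tanh()
            else:
                x = instance_norm_2d(x).relu()
        return x


class PatchDiscriminator(Module):
    """Conditional patch discriminator shared by both modules.

    Hidden 4x4 stride-2 convolutions (instance norm + leaky-ReLU) followed
    by a 1-filter 1x1 stride-1 layer emitting a logit patch map.  The input
    is the channel concatenation of the conditioning image and the image
    under judgement.  ``forward`` returns ``(logits, hidden_features)`` so
    the hidden activations can serve as a trainable feature extractor for
    the perceptual loss.
    """

    def __init__(self, filters: list[int] | None = None, in_channels: int = 6,
                 width: float = 1.0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        base = filters if filters is not None else [64, 128]
        scaled = [max(1, int(round(f * width))) for f in base]
        self.hidden = [
            Conv2d(in_channels if i == 0 else scaled[i - 1], f, 4, 2, rng=rng)
            for i, f in enumerate(scaled)
        ]
        self.out = Conv2d(scaled[-1], 1, 1, 1, rng=rng)
        self._spec = build_patch_discriminator(base, in_channels=in_channels, width=width)

    def spec(self) -> NetworkSpec:
        return self._spec

    def forward(self, condition: Tensor, image: Tensor):
        x = concat([as_tensor(condition), as_tensor(image)], axis=1)
        features: list[Tensor] = []
        for layer in self.hidden:
            x = instance_norm_2d(layer(x)).leaky_relu(0.2)
            features.append(x)
        return self.out(x), features


class MappingNetwork(Module):
    """Latent mapping network (FC-Block) producing AdaIN style parameters.

    Three fully connected layers of constant width (the style-embedding
    filter size) with instance normalisation and ReLU, followed by one
    affine head per AdaIN block emitting a (scale, shift) pair.  Scales are
    emitted as 1 + delta so an untrained network starts near the identity
    style.
    """

    def __init__(self, latent_dim: int = LATENT_DIM, width: int = 512,
                 channels: int = 512, n_blocks: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.latent_dim = latent_dim
        self.fc = [Linear(latent_dim if i == 0 else width, width, rng=rng)
                   for i in range(3)]
        self.heads = [Linear(width, 2 * channels, rng=rng) for _ in range(n_blocks)]
        self.channels = channels

    def forward(self, z) -> list[tuple[Tensor, Tensor]]:
        z = as_tensor(z)
        if z.ndim == 1:
            z = z.reshape(1, -1)
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent vector has dimension {z.shape[1]}, expected {self.latent_dim}"
            )
        x = z
        for layer in self.fc:
            x = instance_norm_1d(layer(x)).relu()
        styles = []
        for head in self.heads:
            params = head(x)
            scale = params[:, : self.channels] + 1.0
            shift = params[:, self.channels :]
            styles.append((scale, shift))
        return styles


class StyleEnhancer(Module):
    """Module-2 generator: image-to-image refinement with style embedding.

    See :func:`modgan.nn.specs.build_module2_generator` for the layer-level
    description.  ``forward(x, styles)`` takes the AdaIN style parameters
    from a :class:`MappingNetwork`; with ``styles=None`` the AdaIN blocks
    receive the identity style (scale 1, shift 0), which is the
    without-style-embedding ablation arm.
    """

    def __init__(self, image_size: int = 256, in_channels: int = 3,
                 out_channels: int = 3, width: float = 1.0,
                 n_adain_blocks: int = 2, dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = [max(1, int(round(f * width))) for f in (64, 128, 256, 512, 512)]
        base = c[-1]
        self.base_channels = base
        self.enc = [Conv2d(in_channels, c[0], 4, 1, rng=rng)]
        self.enc += [Conv2d(c[i - 1], c[i], 4, 2, rng=rng) for i in range(1, 5)]
        self.res = [
            (Conv2d(base, base, 4, 1, rng=rng), Conv2d(base, base, 4, 1, rng=rng))
            for _ in range(3)
        ]
        self.join = Conv2d(2 * base, base, 1, 1, rng=rng)
        self.adain_blocks = [
            (Conv2d(base, base, 4, 1, rng=rng), Conv2d(base, base, 4, 1, rng=rng))
            for _ in range(n_adain_blocks)
        ]
        self.n_adain_blocks = n_adain_blocks
        dec_c = [max(1, int(round(f * width))) for f in (512, 256, 128, 64)]
        self.dec = [ConvTranspose2d(base if i == 0 else dec_c[i - 1], f, 4, 2, rng=rng)
                    for i, f in enumerate(dec_c)]
        self.dec_dropout = [Dropout(dropout, rng=rng) for _ in range(3)]
        self.final = Conv2d(dec_c[-1], out_channels, 4, 1, rng=rng)
        self._spec = build_module2_generator(
            image_size, in_channels, out_channels, width, n_adain_blocks, dropout
        )

    def spec(self) -> NetworkSpec:
        return self._spec

    def forward(self, x: Tensor, styles=None) -> Tensor:
        x = as_tensor(x)
        for layer in self.enc:
            x = instance_norm_2d(layer(x)).relu()
        pre = x
        block_outs = []
        for c1, c2 in self.res:
            x = instance_norm_2d(c1(x)).relu()
            x = instance_norm_2d(c2(x)).relu()
            block_outs.append(x)
        # residual join: pre-block features concatenated with the second
        # block's output, projected back to the base width
        joined = self.join(concat([pre, block_outs[1]], axis=1))
        x = x + joined
        n = x.shape[0]
        if styles is None:
            ones = Tensor(np.ones((n, self.base_channels)))
            zeros = Tensor(np.zeros((n, self.base_channels)))
            styles = [(ones, zeros)] * self.n_adain_blocks
        if len(styles) != self.n_adain_blocks:
            raise ValueError(
                f"expected {self.n_adain_blocks} style pairs, got {len(styles)}"
            )
        for (c1, c2), (scale, shift) in zip(self.adain_blocks, styles):
            skip = x
            h = adain(c1(x), scale, shift).relu()
            x = c2(h) + skip
        for i, layer in enumerate(self.dec):
            x = instance_norm_2d(layer(x))
            if i < 3:
                x = self.dec_dropout[i](x)
            x = x.relu()
        return self.final(x).tanh()


def receptive_field_footprint(spec: NetworkSpec, input_size: int | None = None,
                              rng: np.random.Generator | None = None) -> int:
    """Empirical receptive field via a gradient footprint.

    Runs the conv stack of ``spec`` (random weights, leaky-ReLU, no
    normalisation — instance statistics would couple every spatial
    position) on a random input, backpropagates from the central output
    unit, and returns the side length of the bounding box of non-zero input
    gradient.  Agrees with the recursive formula for interior units.
    """
    from .specs import receptive_field as rf_formula

    rng = rng or np.random.default_rng(0)
    if input_size is None:
        input_size = max(64, 2 * rf_formula(spec))
    x = Tensor(rng.normal(size=(1, 1, input_size, input_size)), requires_grad=True)
    h = x
    for layer in spec.layers:
        if layer.kind != "conv":
            raise ValueError("footprint oracle supports conv-only specs")
        w = Parameter(rng.normal(0.0, 1.0, (1, h.shape[1], layer.kernel, layer.kernel)))
        h = conv2d(h, w, stride=layer.stride, padding="same").leaky_relu(0.2)
    ci, cj = h.shape[2] // 2, h.shape[3] // 2
    g = np.zeros(h.shape)
    g[0, 0, ci, cj] = 1.0
    h.backward(g)
    nz = np.argwhere(np.abs(x.grad[0, 0]) > 1e-12)
    if nz.size == 0:
        return 0
    extent_h = int(nz[:, 0].max() - nz[:, 0].min() + 1)
    extent_w = int(nz[:, 1].max() - nz[:, 1].min() + 1)
    return max(extent_h, extent_w)
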