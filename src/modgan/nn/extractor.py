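"""Pluggable perceptual feature extractors for the style/content losses.

The style and content terms compare images in the feature space of a frozen
five-block convolutional network.  The default extractor here is a
deterministic, fixed-seed randomly initialised convolutional basis: random
convolutional features are a well-behaved perceptual basis (they preserve
texture and edge statistics) and make the losses fully self-contained — no
pretrained weights ship with the package.  Any object with a
``features(image) -> list[Tensor]`` method of B blocks can be substituted.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .layers import Conv2d, Module

__all__ = ["RandomFeatureExtractor", "N_BLOCKS"]

#: number of convolutional blocks tapped for style/content losses; the
#: per-block style weight 1/5 matches this count
N_BLOCKS = 5

_DEFAULT_SEED = 20240829


def _avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        x = x[:, :, : h - h % 2, : w - w % 2]
        n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class RandomFeatureExtractor(Module):
    """Five-block frozen conv net; each block is conv3x3 -> ReLU -> pool2.

    The tap for block *i* is the post-ReLU activation of its convolution
    (before pooling), mirroring how style-transfer losses tap the first
    convolution of each block of a deep classifier.
    """

    def __init__(self, in_channels: int = 3,
                 channels: tuple[int, ...] = (8, 16, 32, 64, 64),
                 seed: int = _DEFAULT_SEED):
        super().__init__()
        if len(channels) != N_BLOCKS:
            raise ValueError(f"extractor must have {N_BLOCKS} blocks")
        rng = np.random.default_rng(seed)
        self.convs = [
            Conv2d(in_channels if i == 0 else channels[i - 1], c, 3, 1, rng=rng)
            for i, c in enumerate(channels)
        ]
        # frozen: exclude from any optimiser by construction (callers never
        # pass extractor.parameters() to an optimiser), but gradients still
        # flow *through* it to the generator.

    def features(self, image: Tensor) -> list[Tensor]:
        """Return the B=5 block activations for an (N, C, H, W) image."""
        x = as_tensor(image)
        taps = []
        for conv in self.convs:
            x = conv(x).relu()
            taps.append(x)
            x = _avg_pool2(x)
        return taps
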