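"""Adversarial and non-adversarial training objectives.

The holistic training loss is a weighted sum of six terms:

    L = L_adv + w1 * L_pix + w2 * L_perc + w3 * L_style + w4 * L_content
        + w5 * L_ssim,          (w1..w5) = (1, 10, 0.0001, 0.0001, 5)

where L_adv is the standard conditional-GAN objective (non-saturating form
for the generator), L_pix is the mean absolute pixel difference, L_perc
matches hidden-layer activations of the discriminator (used as a trainable
feature extractor, per-layer weight 1/2), L_style compares Gram matrices of
a frozen five-block feature extractor (per-block weight 1/5, normalised by
1/(4 d^2) with d the channel depth), L_content compares the raw feature
maps (per-block weight 1, normalised by element count), and L_ssim is one
minus the structural similarity index.

Every function accepts either plain numpy arrays (returning floats) or
autodiff :class:`~modgan.nn.autograd.Tensor` objects (returning tensors the
generator can backpropagate through).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidParameterError, ShapeError
from .nn.autograd import Tensor, as_tensor, conv2d

__all__ = [
    "LossWeights",
    "FeatureMap",
    "GramMatrix",
    "adversarial_loss",
    "pixel_loss",
    "perceptual_feature_loss",
    "gram_matrix",
    "style_loss",
    "content_loss",
    "ssim",
    "ssim_loss",
    "holistic_loss",
    "PERCEPTUAL_LAYER_WEIGHT",
    "STYLE_BLOCK_WEIGHT",
]

PERCEPTUAL_LAYER_WEIGHT = 0.5  # per-discriminator-layer weight
STYLE_BLOCK_WEIGHT = 0.2       # per-extractor-block weight (1/5 for 5 blocks)

_EPS_PROB = 1e-7


@dataclass
class LossWeights:
    """Weights of the non-adversarial terms in the holistic loss."""

    w1: float = 1.0       # pixel
    w2: float = 10.0      # perceptual (feature matching)
    w3: float = 0.0001    # style
    w4: float = 0.0001    # content
    w5: float = 5.0       # ssim

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4, self.w5) < 0:
            raise ConfigError("loss weights must be non-negative")


@dataclass
class FeatureMap:
    """Feature activations with provenance (discriminator layer or
    extractor block)."""

    values: np.ndarray
    source: str = ""


@dataclass
class GramMatrix:
    """Channel-by-channel inner products of a feature map (spatial sum)."""

    values: np.ndarray
    depth: int


def _raw(x):
    if isinstance(x, FeatureMap):
        x = x.values
    return x


def _is_tensor_input(*items) -> bool:
    for it in items:
        if isinstance(it, Tensor):
            return True
        if isinstance(it, (list, tuple)) and any(isinstance(_raw(v), Tensor) for v in it):
            return True
    return False


def _finish(out: Tensor, tensor_mode: bool):
    return out if tensor_mode else out.item()


def _check_same_shape(a, b, what: str):
    if tuple(np.shape(a.data if isinstance(a, Tensor) else a)) != tuple(
        np.shape(b.data if isinstance(b, Tensor) else b)
    ):
        raise ShapeError(f"{what}: operands must share a shape")


# ---------------------------------------------------------------------------


def adversarial_loss(d_real, d_fake, eps: float = _EPS_PROB):
    """Conditional-GAN objective from discriminator probability patch maps.

    Returns ``(discriminator_loss, generator_loss)`` where the
    discriminator loss is the negated log-likelihood of perfect
    real/fake classification and the generator loss is the
    non-saturating form -E[log D(fake)].  Probabilities are clamped to
    [eps, 1 - eps]; expectations are means over patches and batch.
    """
    tensor_mode = _is_tensor_input(d_real, d_fake)
    dr, df = as_tensor(_raw(d_real)), as_tensor(_raw(d_fake))
    if dr.shape != df.shape:
        raise ShapeError("patch maps must share a shape")
    if not (np.isfinite(dr.data).all() and np.isfinite(df.data).all()):
        raise InvalidParameterError("adversarial loss received non-finite values")
    dr = dr.clip(eps, 1.0 - eps)
    df = df.clip(eps, 1.0 - eps)
    d_loss = -(dr.log().mean()) - ((1.0 - df).log().mean())
    g_loss = -(df.log().mean())
    return _finish(d_loss, tensor_mode), _finish(g_loss, tensor_mode)


def pixel_loss(t_hat, t):
    """Mean absolute pixel difference (L1) between generated and target."""
    tensor_mode = _is_tensor_input(t_hat, t)
    a, b = as_tensor(_raw(t_hat)), as_tensor(_raw(t))
    _check_same_shape(a, b, "pixel_loss")
    return _finish((a - b).abs().mean(), tensor_mode)


def perceptual_feature_loss(disc_features_fake, disc_features_real,
                            layer_weight: float = PERCEPTUAL_LAYER_WEIGHT):
    """Discriminator feature matching.

    sum_n w * (1/N_n) * sum |D_n(fake) - D_n(real)| over the L hidden
    layers, with N_n the element count of layer n.
    """
    if len(disc_features_fake) != len(disc_features_real):
        raise ShapeError("feature lists must align layer-by-layer")
    tensor_mode = _is_tensor_input(disc_features_fake, disc_features_real)
    total = as_tensor(0.0)
    for fake, real in zip(disc_features_fake, disc_features_real):
        a, b = as_tensor(_raw(fake)), as_tensor(_raw(real))
        _check_same_shape(a, b, "perceptual_feature_loss")
        total = total + layer_weight * (a - b).abs().mean()
    return _finish(total, tensor_mode)


def gram_matrix(features):
    """Gram matrix of a single-instance feature map (C, H, W).

    G[c, c'] = sum over spatial positions of f_c * f_c'; ``depth`` records
    the channel count used by the style-loss normalisation.
    """
    f = _raw(features)
    tensor_mode = isinstance(f, Tensor)
    t = as_tensor(f)
    if t.ndim == 4:
        if t.shape[0] != 1:
            raise ShapeError("gram_matrix expects a single instance")
        t = t.reshape(t.shape[1], t.shape[2], t.shape[3])
    if t.ndim != 3:
        raise ShapeError("gram_matrix expects (C, H, W) features")
    c = t.shape[0]
    flat = t.reshape(c, -1)
    g = flat @ flat.transpose(1, 0)
    if tensor_mode:
        return g
    return GramMatrix(g.numpy(), depth=c)


def _gram_tensor(t: Tensor) -> tuple[Tensor, int]:
    if t.ndim == 4:
        if t.shape[0] != 1:
            raise ShapeError("style features must be single-instance")
        t = t.reshape(t.shape[1], t.shape[2], t.shape[3])
    c = t.shape[0]
    flat = t.reshape(c, -1)
    return flat @ flat.transpose(1, 0), c


def style_loss(feats_hat, feats_ref, block_weight: float = STYLE_BLOCK_WEIGHT):
    """Squared Frobenius distance between Gram matrices per block.

    sum_i w * 1/(4 d_i^2) * ||Gram_i(hat) - Gram_i(ref)||_F^2, with d_i the
    channel depth of block i.  Invariant to spatial permutations of the
    features within a block.
    """
    if len(feats_hat) != len(feats_ref):
        raise ShapeError("style feature lists must align block-by-block")
    tensor_mode = _is_tensor_input(feats_hat, feats_ref)
    total = as_tensor(0.0)
    for fh, fr in zip(feats_hat, feats_ref):
        a, b = as_tensor(_raw(fh)), as_tensor(_raw(fr))
        _check_same_shape(a, b, "style_loss")
        ga, d = _gram_tensor(a)
        gb, _ = _gram_tensor(b)
        diff = ga - gb
        total = total + (block_weight / (4.0 * d * d)) * (diff * diff).sum()
    return _finish(total, tensor_mode)


def content_loss(feats_hat, feats_ref, block_weight: float = 1.0):
    """Squared Frobenius distance between raw feature maps per block,
    normalised by the element count of each block."""
    if len(feats_hat) != len(feats_ref):
        raise ShapeError("content feature lists must align block-by-block")
    tensor_mode = _is_tensor_input(feats_hat, feats_ref)
    total = as_tensor(0.0)
    for fh, fr in zip(feats_hat, feats_ref):
        a, b = as_tensor(_raw(fh)), as_tensor(_raw(fr))
        _check_same_shape(a, b, "content_loss")
        diff = a - b
        total = total + block_weight * (diff * diff).mean()
    return _finish(total, tensor_mode)


# ---------------------------------------------------------------------------
# structural similarity
# ---------------------------------------------------------------------------


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


_WINDOW = _gaussian_window()
_K1, _K2 = 0.01, 0.03


def _to_nchw(t: Tensor) -> Tensor:
    if t.ndim == 2:
        return t.reshape(1, 1, t.shape[0], t.shape[1])
    if t.ndim == 3 and t.shape[2] == 3:  # HWC image tensor
        return t.transpose(2, 0, 1).reshape(t.shape[2], 1, t.shape[0], t.shape[1])
    if t.ndim == 4:  # NCHW: fold channels into batch
        n, c, h, w = t.shape
        return t.reshape(n * c, 1, h, w)
    raise ShapeError(f"unsupported image shape {t.shape} for SSIM")


def ssim(x, y, data_range: float | None = None):
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5).

    Accepts 2-D images, HxWx3 image tensors or NCHW batches; the local map
    uses valid windows only.  K1 = 0.01, K2 = 0.03.  ``data_range``
    defaults to max - min of the reference ``y`` (2.0 is the conventional
    choice for [-1, 1] network images).
    """
    tensor_mode = _is_tensor_input(x, y)
    a, b = as_tensor(_raw(x)), as_tensor(_raw(y))
    _check_same_shape(a, b, "ssim")
    if data_range is None:
        data_range = float(b.data.max() - b.data.min())
    if data_range <= 0:
        raise InvalidParameterError("data_range must be positive")
    a, b = _to_nchw(a), _to_nchw(b)
    if a.shape[2] < 11 or a.shape[3] < 11:
        raise ShapeError("SSIM requires images of at least 11 x 11 pixels")
    w = Tensor(_WINDOW.reshape(1, 1, 11, 11))
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2

    def filt(t):
        return conv2d(t, w, stride=1, padding="valid")

    mu_x, mu_y = filt(a), filt(b)
    sig_x = filt(a * a) - mu_x * mu_x
    sig_y = filt(b * b) - mu_y * mu_y
    sig_xy = filt(a * b) - mu_x * mu_y
    lum = (2.0 * mu_x * mu_y + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
    cs = (2.0 * sig_xy + c2) / (sig_x + sig_y + c2)
    return _finish((lum * cs).mean(), tensor_mode)


def ssim_loss(t_hat, t, data_range: float = 2.0):
    """1 - SSIM(target, generated); zero iff the images coincide."""
    return 1.0 - ssim(t_hat, t, data_range=data_range)


def holistic_loss(components, weights: LossWeights | None = None):
    """Weighted sum of the six loss terms.

    ``components`` maps term names (``adv``, ``pix``, ``perc``, ``style``,
    ``content``, ``ssim``) to scalars (floats or tensors); missing terms
    count as zero.
    """
    weights = weights or LossWeights()
    comp = dict(components)
    for key, val in comp.items():
        v = val.data if isinstance(val, Tensor) else val
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError(f"loss component {key!r} is not finite")
    zero = 0.0
    total = (
        comp.get("adv", zero)
        + weights.w1 * comp.get("pix", zero)
        + weights.w2 * comp.get("perc", zero)
        + weights.w3 * comp.get("style", zero)
        + weights.w4 * comp.get("content", zero)
        + weights.w5 * comp.get("ssim", zero)
    )
    return total
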