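"""Adversarial training of the two modules and the two-stage inference path.

Training alternates one discriminator update (binary cross-entropy on real
vs generated patches) with one generator update on the holistic weighted
loss.  Module 1 learns sinogram -> coarse image; Module 2 learns coarse
image -> refined image with a per-example latent vector injected through
the style mapping network (switchable off for the without-style-embedding
ablation arm).  Batch size 1 with instance normalisation is the default,
and the image size and network width are configuration parameters so the
identical code runs at desk scale (64 px, narrow) and at full scale
(256 px, the published filter counts).

All randomness flows from the configured seed through named substreams
(initialisation, shuffling, augmentation, latent vectors), which makes the
loss trajectory bit-reproducible in single-threaded runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize

from . import losses
from .errors import InvalidParameterError
from .nn import (
    LATENT_DIM,
    MappingNetwork,
    PatchDiscriminator,
    RandomFeatureExtractor,
    StyleEnhancer,
    Tensor,
    UNetGenerator,
)
from .nn.layers import Adam
from .phantoms import ActivityPhantom, TrainingPair
from .projection import ImageTensor, Sinogram, sinogram_to_network_input

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "TrainHistory",
    "augment",
    "train_module1",
    "train_module2",
    "reconstruct_modular",
    "degrade_image_tensor",
    "make_module2_standin_dataset",
    "evaluate_module1",
    "tensor_from_image",
    "image_from_tensor",
]


@dataclass
class AugmentConfig:
    flip: bool = True
    rotation: bool = True
    warp: bool = True
    intensity: bool = True
    blur: bool = True
    crop: bool = True

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(False, False, False, False, False, False)


@dataclass
class TrainConfig:
    epochs: int = 1
    max_steps: int | None = None
    batch_size: int = 1
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    image_size: int = 64
    width: float = 0.125
    loss_weights: losses.LossWeights = field(default_factory=losses.LossWeights)
    augmentation: AugmentConfig = field(default_factory=AugmentConfig.none)
    style_embedding: bool = True
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidParameterError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be positive")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)
    evaluations: list[dict] = field(default_factory=list)

    def add(self, **record) -> None:
        for key, value in record.items():
            if isinstance(value, float) and not np.isfinite(value):
                raise FloatingPointError(f"non-finite {key} at step {len(self.records)}")
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def component(self, key: str) -> list[float]:
        return [r[key] for r in self.records if key in r]


# ---------------------------------------------------------------------------
# tensor <-> image plumbing
# ---------------------------------------------------------------------------


def tensor_from_image(image: ImageTensor) -> Tensor:
    """(H, W, 3) image tensor -> network batch (1, 3, H, W)."""
    return Tensor(image.values.transpose(2, 0, 1)[None])


def image_from_tensor(t: Tensor, role: str = "output",
                      vmin: float = 0.0, vmax: float = 1.0) -> ImageTensor:
    plane = np.clip(t.data[0], -1.0, 1.0).transpose(1, 2, 0)
    return ImageTensor(plane, role=role, vmin=vmin, vmax=vmax)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def augment(image: ImageTensor, config: AugmentConfig, seed: int = 0) -> ImageTensor:
    """Seeded random composition of the enabled transforms.

    Flips, small rotations, elastic warps, intensity scaling (clipped back
    to [-1, 1]), Gaussian blur, and crop-and-resize; output shape is always
    preserved.  With every toggle off this is the identity.
    """
    plane = image.values[:, :, 0].copy()
    rng = np.random.default_rng(seed)
    h, w = plane.shape
    if config.flip:
        if rng.random() < 0.5:
            plane = plane[:, ::-1]
        if rng.random() < 0.5:
            plane = plane[::-1, :]
    if config.rotation:
        angle = rng.uniform(-15.0, 15.0)
        plane = ndi.rotate(plane, angle, reshape=False, order=1, mode="constant",
                           cval=float(plane.min()))
    if config.warp:
        sigma, alpha = 8.0, 0.08 * h
        dy = ndi.gaussian_filter(rng.normal(size=plane.shape), sigma) * alpha
        dx = ndi.gaussian_filter(rng.normal(size=plane.shape), sigma) * alpha
        yy, xx = np.mgrid[0:h, 0:w]
        plane = ndi.map_coordinates(plane, [yy + dy, xx + dx], order=1,
                                    mode="constant", cval=float(plane.min()))
    if config.intensity:
        plane = plane * rng.uniform(0.8, 1.2) + rng.uniform(-0.1, 0.1)
    if config.blur:
        plane = ndi.gaussian_filter(plane, sigma=rng.uniform(0.0, 1.5))
    if config.crop:
        frac = rng.uniform(0.8, 1.0)
        ch, cw = max(8, int(h * frac)), max(8, int(w * frac))
        oy = rng.integers(0, h - ch + 1)
        ox = rng.integers(0, w - cw + 1)
        plane = _sk_resize(plane[oy : oy + ch, ox : ox + cw], (h, w), order=1,
                           mode="constant", anti_aliasing=False, preserve_range=True)
    plane = np.clip(plane, -1.0, 1.0)
    return ImageTensor(np.repeat(plane[:, :, None], 3, axis=2), role=image.role,
                       vmin=image.vmin, vmax=image.vmax)


def degrade_image_tensor(image: ImageTensor, seed: int = 0,
                         blur_sigma: float = 2.0,
                         noise_sigma: float = 0.3) -> ImageTensor:
    """Blur + additive noise degradation emulating a coarse Module-1 output
    (low-frequency structure retained, detail and SNR lost)."""
    rng = np.random.default_rng(seed)
    plane = ndi.gaussian_filter(image.values[:, :, 0], blur_sigma)
    plane = np.clip(plane + rng.normal(0.0, noise_sigma, plane.shape), -1.0, 1.0)
    return ImageTensor(np.repeat(plane[:, :, None], 3, axis=2), role="module1",
                       vmin=image.vmin, vmax=image.vmax)


def make_module2_standin_dataset(pairs: list[TrainingPair], seed: int = 0,
                                 **degrade_kwargs) -> list[tuple[ImageTensor, ImageTensor]]:
    """(degraded, clean) pairs standing in for Module-1 outputs, decoupling
    Module-2 unit training from Module 1."""
    return [
        (degrade_image_tensor(p.target, seed=seed + i, **degrade_kwargs), p.target)
        for i, p in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    base = np.random.SeedSequence(seed)
    children = base.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _style_content_terms(extractor, fake: Tensor, real: Tensor):
    feats_fake = extractor.features(fake)
    feats_real = extractor.features(real)
    return (losses.style_loss(feats_fake, feats_real),
            losses.content_loss(feats_fake, feats_real))


def _generator_components(disc, extractor, condition, fake, real, weights):
    logits_fake, feats_fake = disc(condition, fake)
    _, feats_real = disc(condition, real)
    adv = -(logits_fake.sigmoid().clip(1e-7, 1 - 1e-7).log().mean())
    comp = {
        "adv": adv,
        "pix": losses.pixel_loss(fake, real),
        "perc": losses.perceptual_feature_loss(feats_fake, feats_real),
        "ssim": losses.ssim_loss(fake, real, data_range=2.0),
    }
    if weights.w3 > 0 or weights.w4 > 0:
        comp["style"], comp["content"] = _style_content_terms(extractor, fake, real)
    return comp


def _disc_step(disc, d_opt, condition, fake_data: np.ndarray, real):
    logits_real, _ = disc(condition, real)
    logits_fake, _ = disc(condition, Tensor(fake_data))
    d_loss, _ = losses.adversarial_loss(
        logits_real.sigmoid(), logits_fake.sigmoid()
    )
    d_opt.zero_grad()
    d_loss.backward()
    d_opt.step()
    return d_loss.item()


def _record_from(components, total, d_loss, step):
    rec = {"step": step, "d_loss": d_loss, "total": total}
    for key, val in components.items():
        rec[key] = val.item() if isinstance(val, Tensor) else float(val)
    return rec


def _maybe_checkpoint(config, step, model, mapping=None):
    if config.checkpoint_every and config.checkpoint_dir and \
            step % config.checkpoint_every == 0:
        from .io import save_checkpoint

        save_checkpoint(model, f"{config.checkpoint_dir}/gen_step{step}",
                        {"step": step, "seed": config.seed})
        if mapping is not None:
            save_checkpoint(mapping, f"{config.checkpoint_dir}/map_step{step}",
                            {"step": step, "seed": config.seed})


def train_module1(dataset: list[TrainingPair], config: TrainConfig):
    """Train the sinogram-to-image module; returns (generator, history)."""
    if not dataset:
        raise InvalidParameterError("dataset must be non-empty")
    rngs = _substreams(config.seed, ("init", "shuffle", "augment"))
    gen = UNetGenerator(config.image_size, width=config.width, rng=rngs["init"])
    disc = PatchDiscriminator(width=config.width, rng=rngs["init"])
    extractor = RandomFeatureExtractor()
    g_opt = Adam(gen.parameters(), lr=config.learning_rate, betas=config.betas)
    d_opt = Adam(disc.parameters(), lr=config.learning_rate, betas=config.betas)
    inputs = [tensor_from_image(sinogram_to_network_input(p.sinogram,
                                                          config.image_size))
              for p in dataset]
    targets_img = [p.target for p in dataset]
    history = TrainHistory()
    step = 0
    done = False
    for _ in range(config.epochs):
        if done:
            break
        order = rngs["shuffle"].permutation(len(dataset))
        for idx in order:
            tgt = targets_img[idx]
            if any(vars(config.augmentation).values()):
                tgt = augment(tgt, config.augmentation,
                              seed=int(rngs["augment"].integers(2**31)))
            real = tensor_from_image(tgt)
            condition = inputs[idx]
            fake = gen(condition)
            d_loss = _disc_step(disc, d_opt, condition, fake.data, real)
            comp = _generator_components(disc, extractor, condition, fake, real,
                                         config.loss_weights)
            total = losses.holistic_loss(comp, config.loss_weights)
            gen.zero_grad()
            disc.zero_grad()
            total.backward()
            g_opt.step()
            step += 1
            history.add(**_record_from(comp, total.item(), d_loss, step))
            _maybe_checkpoint(config, step, gen)
            if config.max_steps and step >= config.max_steps:
                done = True
                break
    return gen, history


def _latent_batch(rng: np.random.Generator, n: int = 1) -> Tensor:
    return Tensor(rng.standard_normal((n, LATENT_DIM)))


def train_module2(dataset: list[tuple[ImageTensor, ImageTensor]],
                  config: TrainConfig):
    """Train the refinement module on (coarse, clean) image pairs.

    Returns (generator, mapping_network, history); ``mapping_network`` is
    None when style embedding is disabled (the ablation arm, in which the
    AdaIN blocks receive the identity style).
    """
    if not dataset:
        raise InvalidParameterError("dataset must be non-empty")
    rngs = _substreams(config.seed, ("init", "shuffle", "augment", "latent"))
    base_channels = max(1, int(round(512 * config.width)))
    gen = StyleEnhancer(config.image_size, width=config.width, rng=rngs["init"])
    mapping = None
    g_params = gen.parameters()
    if config.style_embedding:
        mapping = MappingNetwork(LATENT_DIM, width=base_channels,
                                 channels=base_channels, rng=rngs["init"])
        g_params = g_params + mapping.parameters()
    disc = PatchDiscriminator(width=config.width, rng=rngs["init"])
    extractor = RandomFeatureExtractor()
    g_opt = Adam(g_params, lr=config.learning_rate, betas=config.betas)
    d_opt = Adam(disc.parameters(), lr=config.learning_rate, betas=config.betas)
    history = TrainHistory()
    step = 0
    done = False
    for _ in range(config.epochs):
        if done:
            break
        order = rngs["shuffle"].permutation(len(dataset))
        for idx in order:
            coarse, clean = dataset[idx]
            if any(vars(config.augmentation).values()):
                aug_seed = int(rngs["augment"].integers(2**31))
                coarse = augment(coarse, config.augmentation, seed=aug_seed)
                clean = augment(clean, config.augmentation, seed=aug_seed)
            condition = tensor_from_image(coarse)
            real = tensor_from_image(clean)
            styles = mapping(_latent_batch(rngs["latent"])) if mapping else None
            fake = gen(condition, styles)
            d_loss = _disc_step(disc, d_opt, condition, fake.data, real)
            comp = _generator_components(disc, extractor, condition, fake, real,
                                         config.loss_weights)
            total = losses.holistic_loss(comp, config.loss_weights)
            gen.zero_grad()
            disc.zero_grad()
            if mapping:
                mapping.zero_grad()
            total.backward()
            g_opt.step()
            step += 1
            history.add(**_record_from(comp, total.item(), d_loss, step))
            _maybe_checkpoint(config, step, gen, mapping)
            if config.max_steps and step >= config.max_steps:
                done = True
                break
    return gen, mapping, history


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------


def reconstruct_modular(sino: Sinogram, module1: UNetGenerator,
                        module2: StyleEnhancer | None = None,
                        mapping: MappingNetwork | None = None,
                        z: np.ndarray | None = None, seed: int = 0,
                        norm: tuple[float, float] | None = None) -> ActivityPhantom:
    """Two-stage reconstruction: t' = G1(s); t'' = G2(t', z).

    The network output in [-1, 1] is de-normalized to activity units with
    the supplied (vmin, vmax) metadata (defaulting to [0, 1]) and clamped
    non-negative.  ``z`` defaults to a seeded standard-normal latent; with
    ``module2=None`` the Module-1 output is returned directly.
    """
    size = module1.image_size
    module1.eval()
    x = tensor_from_image(sinogram_to_network_input(sino, size))
    out = module1(x)
    if module2 is not None:
        module2.eval()
        styles = None
        if mapping is not None:
            if z is None:
                z = np.random.default_rng(seed).standard_normal(LATENT_DIM)
            styles = mapping(Tensor(np.atleast_2d(z)))
        out = module2(out, styles)
    module1.train()
    if module2 is not None:
        module2.train()
    vmin, vmax = norm if norm is not None else (0.0, 1.0)
    plane = (out.data[0, 0] + 1.0) * 0.5 * (vmax - vmin) + vmin
    return ActivityPhantom(np.clip(plane, 0.0, None),
                           pixel_size_mm=sino.radial_spacing_mm)


def evaluate_module1(gen: UNetGenerator, pairs: list[TrainingPair]) -> float:
    """Mean SSIM of Module-1 outputs against targets over a fixture set."""
    from .evaluation import ssim_index

    gen.eval()
    scores = []
    for p in pairs:
        x = tensor_from_image(sinogram_to_network_input(p.sinogram, gen.image_size))
        out = gen(x)
        scores.append(ssim_index(out.data[0, 0], p.target.plane, data_range=2.0))
    gen.train()
    return float(np.mean(scores))
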