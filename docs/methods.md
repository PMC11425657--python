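# Methods

## Problem and approach

PET reconstruction maps a sinogram — line-integral projections of the
tracer-activity distribution, indexed by projection angle and radial
offset — back to an image.  `modgan` implements a two-stage generative
approach: **Module 1**, a conditional GAN with a U-Net generator, translates
the sinogram directly into a coarse activity image; **Module 2**, a
style-embedding GAN, refines that coarse image into the final
reconstruction.  Classical filtered backprojection (FBP) and
ordered-subset expectation maximisation (OSEM) are implemented as
baselines, and a synthetic-data layer supplies phantoms, artefacts and
non-clinical training images so that the entire framework runs without any
clinical data.

## Forward model

The projector is a pixel-driven discrete Radon transform: each source
pixel's centre is mapped to its radial coordinate
`r = c - (y - c) sin t + (x - c) cos t` (pivot `c = n // 2`, matching the
conventional FBP rotation centre) and its value is split between the two
neighbouring radial bins with linear-hat weights.  Because the in-range hat
weights of every pixel sum to one, **projection mass is preserved exactly
at every angle** — the total of each projection equals the total image
activity to floating-point precision.  The backprojector gathers with the
same weights, so the pair is an **exactly matched adjoint**: the identity
`<A x, q> = <x, A' q>` holds to round-off.  Sampling plans are cached per
(grid size, angle) under a 300 MB budget.

Consequences used elsewhere:

- **FBP** applies a frequency-domain ramp filter (optionally Hann-apodized)
  per projection, zero-padded to twice the radial length, and backprojects
  with the adjoint, scaled by `pi / (2 N_angles)`.  On a noise-free 128-px
  disc with 360 angles this recovers the phantom with SSIM ≈ 0.91
  quantitatively on the correct activity scale.
- **OSEM** cycles multiplicative EM updates over interleaved angle subsets;
  with one subset it is MLEM bit-for-bit, and the exact adjoint makes the
  Poisson log-likelihood non-decreasing per iteration (asserted in tests
  over 20 iterations).  Defaults: 4 subsets, 10 iterations, epsilon 1e-8
  in the ratio denominator; zero-sensitivity pixels are masked to zero.
- All reconstruction oracles commit the *inverse crime* (data simulated
  with the same discrete projector that reconstructs them); this is
  deliberate for unit-level verification and is the reason desk-scale
  quality figures should not be read as clinical performance.

## Artefact simulation

Three corruption classes stress the networks:

- **Count noise**: the sinogram is scaled to a target total number of
  events and each bin replaced by a Poisson draw (presets low/medium/high =
  1e5/1e6/1e7 counts; any magnitude can be requested).  Expected total
  counts are preserved by construction.
- **Motion**: rigid in-plane rotations (default 2°, 5°, 10°, uniform
  weights summing to one) are applied to the image; the projections of the
  rotated copies are blended as a weighted sum — exactly linear in the
  weights.
- **Attenuation-like signal loss**: circular cavities and an optional wedge
  are zeroed inside chosen tissue labels before projection.  No physical
  attenuation, scatter or randoms modelling is attempted.

## Scanner sinogram reorganisation

Scanner-rebinned sinograms cover 140 angles over [0°, 180°) with 360 radial
bins.  They are extended to 360° coverage with the parallel-beam identity
`p(theta + 180, r) = p(theta, -r)`; on this projector's grid the radial
mirror is a reversal followed by a one-bin roll (mirror about bin
`n // 2`), which makes the identity **bin-exact** against independently
computed opposite-side projections.  The extended sinogram is centrally
cropped (radial margins whose column sums fall below 1e-6 of the maximum),
padded symmetrically to square, bilinearly resized to 256 × 256, min–max
normalized to [−1, 1] and replicated to three channels.  Whether the
140-bin axis is angular or radial is selectable (`angular_axis`).

## Network architectures

Module 1's generator is a U-Net: eight 4×4 stride-2 encoder convolutions
with filter counts 64, 128, 256, 512, 512, 512, 512, 512 (instance
normalisation and leaky-ReLU 0.2 everywhere except the unnormalised first
layer and the plain-ReLU bottleneck), a mirrored transposed-convolution
decoder with skip connections between equal-resolution stages, and a tanh
output.  The discriminator is a patch classifier — 4×4 stride-2
convolutions with 64 and 128 filters, then a 1-filter 1×1 stride-1 output —
whose theoretical receptive field is **10 input pixels**, verified both by
the recursive formula and by a gradient-footprint probe (the probe runs the
conv stack without instance normalisation, whose spatial statistics would
otherwise couple every position).

Module 2's generator comprises a convolutional encoder (64 filters at
stride 1, then 128/256/512/512 at stride 2), three residual blocks of two
512-filter convolutions, a residual join in which the pre-block features
are concatenated with the second block's output and projected back to 512
channels by a 1×1 convolution (the join arithmetic was genuinely open; the
concatenate-and-project reading keeps the decoder contract), two AdaIN
blocks, a transposed-convolution decoder (512/256/128/64, dropout 0.5 on
the first three) and a tanh output convolution.  Style comes from a
**mapping network**: latent noise of dimension 1024 passes through three
fully connected layers of width 512 (instance norm + ReLU), and per-block
affine heads emit the AdaIN scale/shift pairs (scales as `1 + delta` so an
untrained network starts near the identity style).  Disabling style
embedding feeds the AdaIN blocks the identity style — the ablation arm.

All filter counts scale with a width multiplier and the depth adapts to
`log2(image size)`, so the identical code runs the published configuration
at 256 px and a narrow variant at 64 px for desk-scale tests.

The networks run on a compact reverse-mode autodiff engine written for this
package (`modgan.nn.autograd`): numpy tensors with recorded backward
closures, im2col-based convolution/transposed convolution, and the usual
pointwise, reduction and shape ops.  Every primitive is finite-difference
checked in the test suite.

## Training objective

Both modules are trained adversarially, alternating one discriminator
update with one generator update on the holistic loss

    L = L_adv + w1 L_pix + w2 L_perc + w3 L_style + w4 L_content + w5 L_ssim

with weights (w1…w5) = (1, 10, 0.0001, 0.0001, 5).  Terms:

- `L_adv` — binary cross-entropy on sigmoid patch maps; the generator uses
  the non-saturating form −log D(fake).  Probabilities are clamped to
  [1e-7, 1 − 1e-7].
- `L_pix` — mean absolute difference (the printed expectation of a signed
  difference would cancel under averaging; L1 is the standard
  interpretation).
- `L_perc` — discriminator feature matching: per hidden layer, the mean
  absolute difference of activations, weighted 1/2 per layer.
- `L_style` — squared Frobenius distance between Gram matrices
  `G[c, c'] = Σ_spatial f_c f_c'` of a frozen five-block feature extractor,
  weighted 1/5 per block and normalised by `1/(4 d²)` with `d` the channel
  depth.  The Gram matrix is the raw spatial sum (pinned by tests).
- `L_content` — squared Frobenius distance of the raw feature maps,
  normalised by element count.
- `L_ssim` — `1 − SSIM` with an 11×11 Gaussian window (σ 1.5), K1 = 0.01,
  K2 = 0.03, valid-window averaging, data range 2 for [−1, 1] tensors.

The style/content feature extractor is pluggable; the default is a
deterministic fixed-seed randomly initialised five-block convolutional
basis (conv3×3 → ReLU → 2× average pool per block).  Random convolutional
features preserve the texture and edge statistics these losses compare, and
the package ships no pretrained weights.

Optimisation: Adam, learning rate 2e-4, betas (0.5, 0.999), batch size 1
with instance normalisation — the image-translation conventions; all are
exposed in `TrainConfig`.  Augmentation (flips, ≤15° rotations, elastic
warps, intensity scaling, Gaussian blur, crop-and-resize) is seeded and
off by default in the desk-scale runs.  All randomness derives from one
master seed through named substreams (init, shuffle, augment, latent), so
loss trajectories are bit-reproducible single-threaded.

## Synthetic data

- **Brain phantom**: a built-in brain-like tissue geometry (elliptical head,
  peri-brain fat rim, cortical gray-matter band, white-matter interior,
  deep-gray islands, small vessels) painted with relative uptake values.
  Gray matter is fixed at 4× white matter — the contrast of a typical
  FDG scan, derivable from the two-compartment irreversible model
  `Ki = K1 k3 / (k2 + k3)`; the kinetic model sets relative constants only
  (static imaging), not time-activity curves.  Vessels (2.0) and fat (0.5)
  are package defaults — no published values exist — and are configurable.
  Hot lesions are disjoint circles that multiply local uptake by a factor
  > 1, rejection-sampled inside gray/white matter (1000 retries).
- **Image-quality phantom**: a 2-D slice through the sphere centres of the
  standard body phantom — six spheres of 10–37 mm inner diameter on a
  57.2 mm ring, the four smallest hot at 8:1 against a uniform background,
  the two largest and a central 25 mm-radius insert cold.  Defaults:
  147 mm body radius, 256-px grid at 2 mm pixels.
- **Non-clinical training images**: procedurally generated overlapping
  ellipses, random polygons, smoothed-noise textures and iterated
  fractal-like disc clusters, optionally rejection-sampled into target
  ranges of four descriptors: Shannon entropy of the 256-bin intensity
  histogram (bits), mirror symmetry `1 − mean|I − mirror(I)|/range`
  (maximised over both axes), RMS contrast (standard deviation after
  min–max scaling) and the box-counting fractal dimension of the
  Otsu-binarized image.  These are standard formulations; all four are
  pluggable.

What the generator does **not** emulate: detector blur and resolution
modelling (no PSF is applied to ground truth either), attenuation/scatter
physics, 3-D geometry, realistic input functions, inter-subject anatomical
variability.  Passing tests therefore demonstrate the correctness and
internal consistency of the method at desk scale, not clinical image
quality.

## Desk-scale study conditions

Tests and the worked example run at 64 px with a 0.125 width multiplier,
50 training pairs of mixed generator kinds (seed 0), sinograms of 120
angles over 360°.  Module 1 trains for 300 steps.  Module 2 is exercised
two ways: decoupled, on blur-plus-noise degradations standing in for
coarse Module-1 outputs (σ = 2 px blur, additive noise σ = 0.3 on the
[−1, 1] scale — emulating the low SNR of a coarse first-stage output),
and end-to-end, trained on actual Module-1 outputs for 900 steps, the
budget at which the desk-scale refinement reliably converges past the
quality of its input.  Evaluation uses 20 held-out pairs.

## Numerical choices and degenerate inputs

- Min–max normalization of a constant image emits zeros with a warning and
  records the degenerate range for inversion.
- Instance-norm and AdaIN epsilon 1e-5; OSEM division guard 1e-8; Poisson
  log-likelihood offset 1e-8.
- A constant image characterizes as entropy 0, symmetry 1, contrast 0,
  fractal dimension 0, flagged degenerate.
- The paired one-tailed t-test returns (t = 0, p = 0.5) for identically
  zero differences and refuses constant non-zero differences; rRMSE uses
  the L2 norm of the reference by default (mean- and range-normalised
  variants selectable).
- The NEMA background protocol is simplified to 12 circular ROIs of each
  sphere's diameter on a ring in the uniform region (the full standard
  prescribes 60 ROIs over multiple slices).

## Known limitations

2-D only; parallel-beam geometry without attenuation/scatter/randoms;
matched (not scanner-realistic) projector pair; no pretrained perceptual
weights; desk-scale GAN training shows direction-of-effect improvements,
not published-scale image quality; brain-region CNR analysis expects
user-supplied ROI masks (no atlas registration).
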