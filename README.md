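# modgan — modular GAN PET reconstruction

`modgan` reconstructs PET images directly from sinograms with a two-stage
generative network, and ships everything needed to exercise and validate
that idea without clinical data: synthetic phantom and artefact simulators,
classical FBP/OSEM baselines on an exactly matched projector pair, and the
standard image-quality metrics and statistics.

It is aimed at researchers in medical image reconstruction who want a
self-contained, CPU-friendly reference implementation of direct
(sinogram-to-image) GAN reconstruction to study, extend or benchmark
against.

## The method

A sinogram `s` collects the parallel-beam line integrals of the activity
image `t` (the Radon transform).  Instead of inverting the operator
analytically (FBP) or iteratively (OSEM), `modgan` learns the mapping in
two stages:

- **Module 1** — a conditional GAN: a U-Net generator `G1` maps `s` to a
  coarse image `t' = G1(s)`, judged by a patch discriminator whose
  receptive field is 10 input pixels.
- **Module 2** — a style GAN: `G2` refines `t'' = G2(t', z)`, where latent
  noise `z ~ N(0, I)` of dimension 1024 passes through a mapping network
  whose affine heads drive adaptive instance normalisation (AdaIN) blocks
  in the generator bottleneck.

Both modules train on the holistic loss

    L = L_adv + 1·L_pix + 10·L_perc + 0.0001·L_style + 0.0001·L_content + 5·L_ssim

combining the adversarial patch loss, L1 pixel error, discriminator
feature matching, Gram-matrix style and feature content distances, and
`1 − SSIM`.  Training data are procedurally generated non-clinical images
(characterized by entropy, symmetry, contrast and fractal dimension)
paired with their own forward projections.  See `docs/methods.md` for the
full model description, parameter defaults and limitations.

Because no deep-learning framework is assumed, the networks run on a
compact numpy autodiff engine included in the package
(`modgan.nn.autograd`), which is finite-difference verified in the tests.

## Worked example: baselines on a noisy brain phantom

```python
import numpy as np
from modgan.phantoms import toy_brain_tissue_map, make_brain_phantom, insert_lesions
from modgan.projection import radon_forward, add_poisson_noise, Sinogram
from modgan.classical import fbp, osem, OsemConfig
from modgan.evaluation import compare_images

tissue = toy_brain_tissue_map(128, seed=3)
truth = insert_lesions(make_brain_phantom(tissue), n=2, uptake_factor=2.0, seed=7)
angles = np.linspace(0, 360, 360, endpoint=False)
sino = radon_forward(truth, angles)                 # noise-free projections
noisy = add_poisson_noise(sino, total_counts=1e6, seed=0)
scale = 1e6 / sino.values.sum()
noisy = Sinogram(noisy.values / scale, angles)      # back to activity units

for name, rec in [("FBP", fbp(noisy)),
                  ("OSEM", osem(noisy, OsemConfig(n_subsets=4, n_iterations=10)))]:
    m = compare_images(rec.values, truth.values)
    print(f"{name}:  SSIM {m['ssim']:.3f}   PSNR {m['psnr_db']:.2f} dB   rRMSE {m['rrmse']:.3f}")
```

prints

```
FBP:  SSIM 0.239   PSNR 19.59 dB   rRMSE 0.455
OSEM:  SSIM 0.760   PSNR 25.03 dB   rRMSE 0.243
```

The brain phantom paints gray matter at 4× white-matter uptake and inserts
two hot lesions at twice the local uptake; at a million counts the ramp
filter amplifies Poisson noise (low SSIM, rRMSE 0.46) while ten OSEM
iterations over four subsets suppress it.  The GAN pipeline is exercised
the same way at desk scale (64 px, narrow networks) by the test suite and
the demo pipeline:

```bash
modgan pipeline --config configs/demo.yaml --out runs/demo
```

which simulates training pairs, trains both modules briefly, reconstructs
held-out sinograms with the modular network plus FBP/OSEM baselines, and
writes `metrics.csv` and a reproducibility manifest.  Other entry points:
`modgan simulate`, `modgan train`, `modgan reconstruct`, `modgan evaluate`,
`modgan validate`.

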