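# srdenoise

Boundary-preserving denoising for low-photon-budget multiphoton microscopy
images — three-photon fluorescence (3PF) of stained nuclei and label-free
third-harmonic generation (THG) of cytoplasmic lipid granules.

At high frame rates or depth, nonlinear microscopy operates in a
*stochastic-resonance* regime: the detected value of a pixel is

```
y = S + V − T   if S + V > T
y = 0           otherwise
```

where `S` is the true signal, `T` the detection threshold, and the noise
`V` combines signal-dependent Poisson shot noise with detector Gaussian
noise. Because `T > S` over much of the field, dim structures are visible
only when noise boosts them across the threshold — so the noise carries
signal, and conventional de-speckling erodes exactly the regions a
segmentation needs. This package provides:

- **`phantom`** — synthetic clean images emulating the two modalities
  (textured elliptical nuclei; granule-studded cytoplasmic disks) with
  ground-truth cell masks;
- **`noise`** — the thresholded Poisson+Gaussian acquisition simulator;
  averaging `N` frames of a location yields the *low-noise answer* used as
  the training and evaluation target (in place of unobtainable noise-free
  ground truth);
- **`ddae`** — a compact fully convolutional denoising autoencoder
  (encoder: conv/ReLU/2× pool stages with `m·2^s` filters; mirrored
  decoder; single-filter linear head), trained with per-pixel MSE, early
  stopping (patience 10) and best-weight restore;
- **`crossval`** — the repeated 5-fold cross-validation protocol over
  acquisition batches;
- **`baselines`** — Gaussian and median filters (σ ∈ {1, 3, 5, 10}) and a
  pluggable BM3D backend, with sigma sweeps selected by average PSNR;
- **`metrics`** — PSNR and SSIM (Gaussian-weighted 11-pixel window);
- **`boundary`** — the boundary-preservation pipeline: histogram
  equalization → IsoData binarization of the denoised image and answer →
  confusion masks → precision `= count_AND/count_O`, recall
  `= count_AND/count_Ans`, specificity `= count_NOR/count_IAns`,
  F-measure (harmonic mean), plus blue/magenta/green overlays;
- **`tiffio` / `cli`** — multi-page TIFF I/O with JSON metadata and an
  end-to-end command line (`simulate / train / denoise / baseline /
  evaluate / crossval`).

## Worked example

```python
import numpy as np
from srdenoise import (AcquisitionParams, DenoiserConfig, acquire_stack,
                       build_ddae, denoise, evaluate_boundary, make_answer,
                       make_nuclei_phantom, psnr, train)
from srdenoise.phantom import PhantomParams

clean = make_nuclei_phantom(PhantomParams(image_size=512, n_objects=24, seed=1).scaled_to(64))
stack = acquire_stack(clean, AcquisitionParams(n_frames=16, seed=2))
answer = make_answer(stack)

config = DenoiserConfig(m=8, epochs=30, patience=10, learning_rate=2e-3, seed=1)
model = build_ddae(config)
pairs = [(f, answer.pixels) for f in stack.frames]
train(model, pairs, config, val_pairs=pairs[:3])

noisy = stack.frames[0]
den = denoise(model, noisy)
print(f"PSNR noisy   {psnr(noisy, answer.pixels):.2f} dB")
print(f"PSNR denoised {psnr(den, answer.pixels):.2f} dB")
print(f"F noisy    {evaluate_boundary(noisy, answer.pixels)[0].f_measure:.3f}")
print(f"F denoised {evaluate_boundary(den, answer.pixels)[0].f_measure:.3f}")
```

prints

```
PSNR noisy   14.69 dB
PSNR denoised 19.50 dB
F noisy    0.705
F denoised 0.899
```

i.e. training on a single 16-frame location already recovers ~5 dB of
signal-to-noise against the frame-averaged answer and raises the
boundary F-measure — the noisy frame's binarized mask matches the
answer's mask at F ≈ 0.71, the denoised frame's at ≈ 0.90.

The same workflow from the shell:

```bash
srdenoise simulate --modality 3pf --n-batches 6 --frames 16 --size 64 --seed 1 --out runs/sim
srdenoise crossval --data runs/sim --out runs/cv --m 8 --epochs 20 --repeats 1
srdenoise evaluate --test runs/sim/answer_00.tif --answer runs/sim/answer_00.tif --out runs/eval
```

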