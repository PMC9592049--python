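# Methods

## The acquisition model

A detected pixel is modelled as a hard-thresholded superposition of true
signal and noise:

```
y = S + V − T   if S + V > T,    y = 0 otherwise
V = (Poisson(g·S)/g − S) + Normal(0, σ)
```

`S` is the clean intensity (arbitrary linear units), `T` the detection
threshold of the photodetection chain, `σ` the detector (thermal/flicker)
noise standard deviation, and `g` the photon gain in photons per intensity
unit (`g = 0` disables shot noise). The Poisson term is re-centred to zero
mean so the model stays additive-then-thresholded; its variance `S/g`
retains the signal dependence of shot noise. The threshold is applied once,
after both noise components are summed.

In the stochastic-resonance regime — noise comparable to or larger than the
signal and `T > S` over much of the field — sub-threshold structure is
detectable only because noise occasionally pushes it across `T`. Averaging
`N` frames of the same location (library default `N = 200`; the scaled-down
test conditions use 8–16) produces the *low-noise answer*, the regression
target and evaluation reference. Key consequences honoured by the model and
asserted in tests: all outputs are non-negative; raising `T` under a fixed
random stream never increases any pixel; a sub-threshold constant field has
a strictly positive answer mean when `σ > 0` and is exactly zero when the
noise is off; answer variance falls as `1/N`.

Default noise parameters (`T = 60`, `σ = 40`, `g = 0.25` against a
foreground level of ≈ 100) were fixed once to realize that regime: dim
foreground (and all background) sits below threshold, and single-frame
fidelity against the answer is poor (≈ 13–15 dB PSNR), leaving the noise —
not the phantom — as the dominant image feature, which is the operating
point the denoiser is meant for.

Randomness: each frame draws from its own `SeedSequence(seed).spawn(i)`
substream, so stacks are reproducible and frame `i`'s content does not
depend on how many frames were acquired before it.

## Synthetic phantoms

No reference data accompany the imaging protocol this package emulates, so
the generators are first-class, parameterized models of the two
modalities' qualitative appearance:

- **Nuclei (3PF)**: rotated ellipses with semi-axes drawn from
  `radius_range`, filled with a smooth multiplicative Gaussian-field
  texture (±20 %, clipped away from zero) on a constant background.
- **Granule clusters (THG)**: per cell, a dim cytoplasmic disk (default
  0.5× the granule intensity) studded with small bright puncta covering a
  target ~12 % of the disk; the *cell mask* is the disk, matching what the
  boundary analysis scores.

Object centres are rejection-sampled with a minimum separation of one mean
radius; touching or partially overlapping boundaries are allowed, as in
confluent culture fields. Two geometry choices matter downstream and were
made a priori from analysis of the evaluation pipeline, not fitted:

1. **~50 % foreground coverage** (default geometry yields ≈ 0.45–0.55).
   Histogram equalization maps pixel values onto their rank CDF, so the
   IsoData threshold of an equalized image sits near the median rank; the
   binarized answer traces the true boundary exactly when foreground
   occupies about half the field. This matches the confluent fields of
   view the protocol targets; at sparse coverage the equalize→IsoData
   binarization over-segments background by construction.
2. **Cytoplasm at 0.5× granule intensity** in the THG phantom, so the
   background/cytoplasm contrast (rather than the cytoplasm/granule
   contrast) dominates the histogram split and a global threshold of the
   *clean* image recovers the cell disk (measured F ≥ 0.99; the test floor
   is 0.95).

Morphology parameters (object counts, radii, texture scale) are free
parameters with documented defaults; they are not estimates of any real
culture's morphometry. `PhantomParams.scaled_to(size)` rescales the
512-pixel default geometry proportionally so tests run at 32–64 px.

## The denoising autoencoder

A symmetric fully convolutional encoder–decoder, single channel in and
out: `depth` encoder stages (k×k convolution with `m·2^s` filters, ReLU,
2× average pooling), mirrored decoder stages (2× nearest-neighbour
upsampling, convolution, ReLU) and a final single-filter linear
convolution. No fully connected layers, so any input with sides divisible
by `2^depth` is accepted; incompatible shapes raise an error naming the
required padded size. Defaults: `depth = 2`, `k = 3`, `m ∈ {8, 16, 32}`
(default 16), ≈ 4.8 k parameters at `m = 8` — deliberately compact, since
the mapping to learn is a local one.

Training pairs every frame of a stack with that stack's single answer.
Loss is per-pixel MSE; the optimizer is Adam at 1e-3 (the standard choice
for this model family — the protocol does not pin one); the epoch budget
is 50 with early stopping at patience 10 on a held-out validation set and
restoration of the best-validation weights. Inputs are normalized by the
maximum of the training answers (or z-scored, configurable); the
statistics are stored on the model so inference inverts them exactly, and
outputs are clipped at zero. Everything — initialization, shuffling,
validation split — derives from the config seed, so training is
bit-reproducible.

The network, its gradients and Adam are implemented directly on numpy
(im2col convolutions); the engine implements exactly the four layer types
the architecture needs and is validated by contract tests (shape
preservation, bias-only degenerate output, monotone parameter counts,
learnability of the identity task, plateau-triggered early stopping).

## Cross-validation protocol

Batches (one location each) are partitioned into 5 folds, re-randomized
per repeat (3 repeats by default). Per fold: the held-out fold is the test
set, one of the remaining folds (seeded draw) is the validation set, the
rest train the model. Three frames per test batch are scored against the
batch answer — PSNR, SSIM, and the boundary F-measure for both the noisy
frame and its denoised output — and grand averages pool all rows. The
plan validator asserts disjoint, exhaustive folds with every batch tested
exactly once per repeat.

## Evaluation

**PSNR** `= 10·log10(data_range²/MSE)`; identical images report an
infinite sentinel (serialized as `null` with `identical: true`).
**SSIM** uses the Gaussian-weighted 11-pixel window (σ = 1.5), K1 = 0.01,
K2 = 0.03, population covariances, and excludes a one-radius border —
the reference convention, cross-checked against scikit-image to 1e-6.
`data_range` defaults to the answer's max − min per comparison (answers
are float frame-means with no canonical full scale) and is recorded in
every report.

**Boundary pipeline**: both images are linearly rescaled to [0, 255],
histogram-equalized over 256 bins, and *independently* binarized at their
IsoData thresholds. IsoData here is the Ridler–Calvard fixed point
iterated on intensities from the mid-range, with inclusive means on the
low side and convergence at half a bin width — conventions differ subtly
between implementations, so an exhaustive fixed-point search over the 256
candidate bins serves as the arbiter in tests. Confusion masks (AND = true
positive, NOR = true negative, plus false positives/negatives) yield
precision, recall, specificity and F; degenerate denominators return NaN
with an explicit reason, never a silent zero. The overlay paints
TP blue, FP magenta, FN green.

## Numerical and I/O choices

- CNN math in float32; metrics and simulation in float64.
- Baseline filters use reflective boundaries; the median filter's
  parameter is conventionally called σ but is the window size in pixels.
- BM3D is a pluggable backend (the algorithm is third-party); without a
  registered backend the call raises a capability error rather than
  silently substituting another filter. Sigma is interpreted on the native
  intensity scale and rescaled to the backend's [0, 1] convention.
- TIFF stacks are uncompressed, one page per frame, metadata as JSON in
  the description tag; 16-bit is canonical for simulated acquisitions,
  float32 for answers and denoised outputs. Integer writes never rescale
  or clip silently. Sweep ties are broken toward the smaller sigma.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the pipeline is implemented faithfully and
that, under the stated noise model, the autoencoder recovers several dB of
PSNR and a large boundary-F margin over raw frames (≈ +4.5 dB and
+0.18 F at the scaled-down study conditions). They do not certify
performance on real microscopy: the phantom lacks optical point-spread
blur, scan-line correlations, drift between frames, and real nuclear or
granule morphology, and its noise — i.i.d. per pixel given the clean
signal — is kinder to linear smoothing than real structured noise. Indeed,
at these conditions a well-tuned Gaussian filter matches or slightly
exceeds the autoencoder on both PSNR and F; the autoencoder's practical
advantages (no per-image parameter sweep, learned nonlinear response to
thresholded noise) manifest on real stochastic-resonance data rather than
on this generator. Problem sizes in tests (64×64, 16 frames, 6 batches;
5-fold CV with `m = 8`, ≤ 20 epochs) are the package's scaled-down study
conditions; the library defaults (512², 200 frames, 31 batches) mirror the
full protocol.
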