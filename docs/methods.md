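# Methods

## Problem setting

A population of early-visual neurons (retinal ganglion cells or V1 units)
responds to a grayscale stimulus; the decoding task is to reconstruct the
stimulus image from the population's binned spike counts. The package
implements the decoder, its composite training objective, the four-metric
evaluation protocol, and a simulator that generates statistically matched
synthetic recordings so the whole pipeline runs and is tested without any
external data.

## Decoder architecture

Input is the spike-count matrix (neurons × time bins), standardised per
neuron (mean/variance estimated on the training split only) and flattened.
Two fully connected layers follow — a hidden layer (default 512 units) and
an output layer sized to the image — whose output is reshaped to a
one-channel image. A convolutional autoencoder then refines it:

* first convolution: a Gabor filter bank (below), stride 1,
  size-preserving zero padding;
* encoder: four convolution blocks, kernel 4, stride 2, padding 1,
  channels 128/256/512/512 by default, LeakyReLU (slope 0.2) and dropout
  (p = 0.5) after each block;
* decoder: four transposed-convolution blocks mirroring the encoder
  (512/256/128/1), LeakyReLU between blocks, sigmoid at the output so
  pixels live in [0, 1].

Kernel size 4 with stride 2 / padding 1 gives exact spatial halving and
doubling, which is why image sides must be divisible by 2⁴. The channel
widths, stride and padding follow the published architecture; kernel size,
LeakyReLU slope, hidden width, sigmoid output and dropout placement
(encoder only) are implementation choices where the source left them open.

Optimisation is Adam (β = 0.9/0.999) with the stepped schedule
lr(epoch) = lr₀ · γ^⌊epoch/E⌋, defaults lr₀ = 0.02, γ = 0.9, E = 100.

### Gabor first layer

A Gabor kernel is a Gaussian envelope times a cosine carrier,
parameterised by orientation θ, wavelength λ, phase ψ, envelope scale σ and
aspect ratio γ. The default bank spans orientations [0, π) in 30° steps at
kernel sizes 7/9/11/13 (24 kernels); per scale, λ = ksize/2, σ = 0.56λ
(≈1.5-octave V1-like bandwidth), aspect 0.5, even phase ψ = 0. Even-phase
Gabors are π-periodic in orientation, so [0, π) covers all distinct
orientations without duplicates.

Every kernel is DC-corrected by subtracting its envelope-weighted mean, so
a constant input drives exactly zero response wherever the kernel support
fits inside the image (at the zero-padded border the constant image
effectively has an edge, so small border responses remain — visible in the
tests, which therefore assert interior response only).

Two integration modes exist: **fixed** (default — the bank *is* the first
convolution, non-trainable) and **modulated** (trainable kernels multiplied
elementwise by the bank at each forward pass, for ablation studies).

## Loss

L = μ·(−SSIM(x, y)) + (1 − μ)·(1/HW)·Σᵢⱼ Wᵢⱼ (xᵢⱼ − yᵢⱼ)², default μ = 0.1.

* The SSIM term uses the *global* (single whole-image window) form by
  default, matching the closed-form definition from which the loss is
  built; a Gaussian-window variant (valid-window local statistics) is
  available as a config option.
* W is built by placing a unit-peak isotropic Gaussian at every neuron's
  RF centre and summing; overlapping RFs add, encoding "more neurons watch
  this pixel ⇒ its error matters more". W is normalised to mean 1 so that
  for spatially uniform error the weighted MSE equals the plain MSE and μ
  keeps the same meaning across images. ON/OFF polarity does not enter W.
  When RF sizes are unknown, σ defaults to (image short side)/8.
* Inside the loss, images are on the unit scale (SSIM constants computed
  with P = 1) so both terms have comparable magnitude; evaluation metrics
  are reported on the 0–255 scale.

Both terms are differentiated by the package's reverse-mode engine; a
finite-difference check in the test suite verifies the gradient to 1e-4
relative tolerance.

Ablations: μ = 0 with uniform W and a plain learned first convolution is
"method 1" (MSE autoencoder); μ = 1 is "method 2" (SSIM autoencoder). With
those settings the "proposed" code path is bitwise-identical to method 1
(uniform weights are cast to the image dtype so multiplying by 1 is a
no-op), which the acceptance suite exploits as an exact trajectory check.

## Evaluation metrics

* **MSE** — mean squared pixel difference; also reported summed over pixels
  per image (`mse_sum`), the convention used in per-image error tables.
* **PSNR** — 10·log₁₀(P²/MSE), P = 255 for 8-bit data; identical images
  return +∞ rather than raising so batch evaluation stays total.
* **SSIM** — luminance × contrast × structure with c₁ = (0.01P)²,
  c₂ = (0.03P)², c₃ = c₂/2, exponents 1. `ssim_global` uses whole-image
  population moments (the form inside the loss); `ssim_windowed` is the
  evaluation-grade 11×11 Gaussian (σ = 1.5) sliding-window mean with
  population-weighted local statistics, verified to 1e-9 against
  scikit-image's Wang-convention implementation. Evaluation reports use the
  windowed form.
* **VIFP** — pixel-domain visual information fidelity: at each dyadic
  scale, Gaussian-window local statistics fit a gain + additive-noise
  channel, and the metric is the ratio of information retained by the
  distorted image to that in the reference (σ²ₙ = 2). The canonical window
  ladder is 17/9/5/3 over four scales; for images too small for a 17-tap
  window the ladder shortens automatically (a 16×16 image uses 9/5/3).

## The simulator

Linear–nonlinear–Poisson units: each neuron has an isotropic Gaussian RF
(centre uniform over the image, σ ∈ [2.5, 5] px by default) with ON or OFF
polarity; its drive is the polarity-signed, mass-normalised RF inner
product with the stimulus contrast (pixels mapped to [−1, 1] about
mid-gray, so mid-gray is the null stimulus); rate = baseline +
gain·ReLU(drive) (softplus/exponential options exist); spike counts over
the stimulus-locked window are Poisson, with timestamps uniform in the
window. All draws come from one seeded generator, so datasets are
bit-reproducible.

Stimuli are disc-windowed sinusoidal gratings (orientation, cycles, phase,
diameter controllable) and random-phase 1/f images whose amplitude spectrum
falls as f^(−exponent) (power as f^(−2·exponent)), contrast-normalised to
span [0, 255].

The **easy benchmark preset** (60 neurons, 32×32 images, 90 % ON, gain
100–150 spk/s per unit drive, baseline ≤ 1 spk/s, 1 s window at 10 ms bins,
stimulus mix half gratings / half 1/f images with spectral exponent 1.8 and
grating frequencies within the population's RF passband) is constructed so
that a closed-form ridge regression from counts to pixels already achieves
mean held-out pixel correlation well above 0.4. That floor is asserted in
the tests: if the data were not linearly decodable, a failure of the
network would be uninterpretable.

What the simulator deliberately omits: surround modulation, noise
correlations between neurons, spike-history dependence, difference-of-
Gaussians RFs, and temporal stimulus structure. Passing tests therefore
demonstrate that the pipeline recovers images when its own generative
assumptions hold — they do not certify performance on real recordings,
where those effects are present.

## Desk-scale study conditions

The end-to-end checks train on 300 stimuli (240/60 split) for 50 epochs at
minibatch 32, the problem size at which the full three-method comparison
runs in minutes on one CPU. `DecoderConfig.desk_scale` shrinks only
capacity and step size, not structure: channels 8/16/16/16 ↔ 16/16/8/1,
128 hidden units, a 4-orientation × 2-scale Gabor bank, and lr₀ = 2e-3.
The published lr₀ = 0.02 remains the config default and defines the
schedule, but at minibatch 32 on this small network Adam at 0.02
oscillates without converging, so the desk configuration uses the smaller
step. Under these conditions the proposed decoder matches or beats the
plain-MSE autoencoder on held-out SSIM in most seeds while keeping the
lowest MSE — the same ordering the method was designed to produce at full
scale.

## Numerical choices

* Network arithmetic is float32; metrics and the weight matrix are float64.
* Per-neuron standardisation guards against zero variance with a 1e-6
  floor; sqrt gradients are floored at 1e-30; sigmoid inputs are clipped at
  ±60 before exponentiation.
* Spike binning uses half-open intervals [bΔ, (b+1)Δ); a spike exactly at a
  bin edge belongs to the later bin, and spikes at/after the window end are
  dropped.
* Train/test splits are floor-sized (⌊0.8·N⌋) over a seeded permutation.
* Image resizing uses PIL box (area) interpolation — deterministic across
  platforms.
* PSNR of a zero-error pair is +∞ by design; mean PSNR over a batch
  averages the finite values only.

## Known limitations

* The global-SSIM loss ignores spatial locality of structure; the windowed
  loss variant is available but slower.
* Zero padding in all convolutions leaks border effects (see the Gabor DC
  note above).
* The numpy engine is single-threaded BLAS-bound; it is sized for the
  desk-scale study, not for the full 100-neuron/10⁵-sample regime the
  original recordings would require.
* `compare_methods` trains each variant once per seed; at desk scale the
  run-to-run spread is nonzero, which is why the comparison is asserted
  directionally over seeds rather than per-seed.
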