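# Methods

`fenoct` implements a self-supervised denoising pipeline for MEMS-OCT
B-scans. No clean reference images are required at any stage: training
supervision comes from the image's own noise statistics, and evaluation
against true clean images is possible only on synthetic phantoms.

## Noise model and phantom generator

MEMS-OCT B-scans carry three characteristic degradations, and the phantom
generator injects exactly these, keeping every component field for oracle
testing:

* **Multiplicative speckle.** Fully developed speckle is modelled as
  i.i.d. unit-mean Gamma(k, 1/k) multiplicative noise with variance `1/k`.
  The default shape `k = 4` (variance 0.25) is a strong but realistic
  speckle level for structural OCT. The Gamma intensity model is the
  standard choice when a single parameter should control speckle contrast.
* **Periodic background.** A sum of 2D illumination-bias components with
  random phases and periods ≥ 4 px (default: one 64-px axial period,
  amplitude 10% of the dynamic range), emulating swept-source and
  scan-mirror instability. Each component is non-negative, `A·(1 + cos)`:
  illumination bias is an intensity offset, and a zero-mean sinusoid would
  clip against zero in the dark air band, turning the clean spectral line
  into a harmonic-rich waveform no notch can remove. The field is
  band-limited by construction.
* **Coherent stripes.** Full-length constant lines of width 1–2 px
  (default: 3 stripes, amplitude 0.35), with seed-stable positions so a
  volume of consecutive B-scans shares stripe positions while speckle
  decorrelates — the property the stripe remover exploits.

The clean phantom is a stack of horizontal intensity bands with smoothly
curved boundaries beneath a dark "air" band (15% of the height by
default); band intensities are evenly spaced over (0.25, 0.8) and
shuffled, so bands are mutually distinct. Corruption is composed as
`noisy = clip(clean·speckle + background + stripes)` with a single clip at
the end, so the stored component fields reproduce the noisy image exactly.

What the phantoms do **not** model: interferometric image formation,
depth-dependent attenuation and roll-off, real tissue texture, and motion.
Passing tests therefore demonstrate that the pipeline removes the modelled
artifact classes under controlled conditions, not clinical performance.

With these defaults a noisy phantom scores roughly 13 dB PSNR against its
clean counterpart — a harsher regime than typical pre-processed clinical
scans, dominated by the k = 4 speckle term.

## Classical preprocessing

**Stripe removal** works on the per-pixel mean of a stack of consecutive
B-scans (default 8): stripes are stack-consistent while tissue speckle
averages down. Each line (row and column orientations are both scanned)
receives a *two-sided spike score*: its sign-consistent deviation from the
medians of the three lines on either side. Thin stripes deviate in the
same direction from both neighbourhoods; tissue-layer step edges deviate
one-sidedly and score ≈ 0, which is why a plain median-filter baseline is
not used — it flags every layer boundary. The automatic threshold is
`max(2 × Q75(|scores|), 5% of the dynamic range)`; the spike score is
exactly zero for most lines, so MAD-based scales degenerate. A refinement
pass unflags lines whose median profile already matches the interpolation
of unflagged neighbours (lines sandwiched between two stripes). Flagged
lines are replaced per scan by linear interpolation along the
perpendicular axis (or by a median-filter baseline, configurable).

In the composed pipeline, stripe *detection* runs on copies with the
axis-aligned periodic background subtracted, because the spike statistic
cannot tell the peak line of a short-period sinusoid from a faint wide
stripe. The subtraction uses a trimmed least-squares Fourier fit to the
median line profiles at the detected notch frequencies — stripe lines
drop out of the fit as outliers. A notch filter cannot build this
detection copy: it would absorb part of each stripe's own spectral comb
and ring the stripes into their neighbours. Replacement always happens in
the original scans, where stripes are still sharp impulses; the notch
filter then runs on the destriped scans, and any de-ringing blur runs
last.

Known limitations: a stripe that coincides with a layer boundary of
similar contrast is ambiguous under this statistic and may be missed;
stripes weaker than 5% of the dynamic range are deliberately left to the
learning stage; a stripe pushed into range saturation by bright tissue
plus illumination bias is partially erased by clipping before any
processing sees it.

**Periodic-noise removal** detects the dominant off-DC peaks of the
centred log-magnitude spectrum (local maxima above a robust floor, a DC
exclusion disk, conjugate pairs reported once) and attenuates them with
*Gaussian-profile* notches `1 − depth·exp(−d²/2r²)` applied at each peak
and its conjugate twin. Smooth notches are used instead of ideal binary
ones because sharp spectral edges ring in the spatial domain; an optional
spatial Gaussian blur remains as a second defence. The filter mask is
conjugate-symmetric by construction, so the output is real to numerical
precision.

## Neighbour subsampling

A noisy image y is partitioned into non-overlapping 2×2 cells; sub-image
g1 takes one fixed pixel of each cell and g2 an adjacent one
(Chebyshev distance ≤ 1, i.e. a subsampling stride of 2). The default
pattern "A" pairs top-left with top-right: the split direction is lateral,
so axial layer boundaries — the anatomy OCT cares about — appear at the
same (±1) row in both halves. The mapping is a pure function of shape and
pattern id: no randomness anywhere, identical across training, validation
and test, which makes g2 a stable pseudo-clean reference for evaluation.
Three other adjacent patterns are available for ablations.

## Network

A 4-level encoder/decoder with skip connections (channels 32/64/128/256
by default, doubling per level):

* **WSPM** — orthonormal single-level Haar analysis into LL/LH/HL/HH; the
  LL band passes through a learnable 1×1 channel-mixing map initialised to
  identity; the detail bands are scaled by (1 − λ), λ = 0.65 by default;
  exact Haar synthesis restores the resolution. With λ = 0 the module is
  the identity; with λ = 1 it reconstructs 2×2 block averages. The module
  is linear in its input for a fixed refiner — no normalisation or
  activation sits in the spectral path, and tests assert this.
* **FE-RFB** — four parallel branches (1×1 reduction to C/4 channels,
  3×3 convolution with dilation 1/2/3/5 and shape-preserving zero padding,
  each convolution followed by group norm and leaky ReLU, then the
  embedded WSPM), concatenated, fused by a 1×1 convolution back to C
  channels, and residual-added to the input. The branch count and rates
  follow the receptive-field-block convention and are configurable. The
  branch convolutions are normalised like every other convolution in the
  network — an early variant without normalisation inside the branches
  trained markedly slower than the plain-block ablations, which confounded
  architecture comparisons.
* **Downsampling** is 2×2 max pooling (a low-pass wavelet pooling variant
  is available behind a config flag, off by default, keeping WSPM the sole
  frequency-selective element in the default model).
* **Upsampling** is bilinear ×2 followed by a 3×3 convolution (avoiding
  the grid artifacts of transposed convolutions). After concatenation with
  the skip tensor the channel count doubles; a 1×1 fusion convolution
  reduces it back to the skip's count before the decoder block, keeping
  the block contract (same channels in and out) and the decoder cost
  symmetric to the encoder.

Ablation switches reproduce the structural variants: `no_wspm` (branches
skip the spectral refinement), `no_ferfb` (blocks replaced by plain
two-layer 3×3 convolution blocks, which also removes the embedded WSPMs),
and `n2n_baseline` (plain blocks plus the original neighbour-subsampling
objective).

Everything runs on a small in-repo reverse-mode autodiff engine over
numpy (`fenoct.autodiff`): dense/dilated convolution via im2col and BLAS
matmuls, exact adjoints for the orthonormal Haar pair, and an Adam
implementation. Every primitive's gradient is checked against central
finite differences in the test suite. Float32 is used for training,
float64 for the numerical tests.

## Objective

    L_total = λ1·L1 + λ2·L2 + λ3·L_freq + γ·L_reg,   (λ1, λ2, λ3, γ) = (0.8, 0.1, 0.1, 0.01)

* `L1 = mean |f(g1(y)) − g2(y)|` — sub-image prediction (L1 for edge
  preservation).
* `L2 = mean (f(g1(y)) − f(g2(y)))²` — both halves must denoise to the
  same estimate.
* `L_freq = mean |F(f(y)) − F(x_pseudo)|²` with F the *orthonormal* 2D
  Fourier transform, normalised by pixel count so the value is
  resolution-independent (and equal to the spatial MSE by Parseval — the
  tests exploit this as an oracle). The pseudo-clean image `x_pseudo` is
  the average of the complementary pair replicated to full size: averaging
  halves independent-noise variance and matches the full-resolution
  output's shape.
* `L_reg = mean ((f(g1(y)) − g2(y)) − (g1(f(y)) − g2(f(y))))²` — the
  neighbour-subsampling consistency regulariser, zero for the identity
  model, which counteracts over-smoothing.

No gradient detachment is applied on either path of `L_freq`/`L_reg`. A
grid-search utility over the λ weights (step 0.1, selecting maximum
validation SSIM) is provided for re-calibration studies.

## Training and evaluation

Adam (β = 0.9/0.999). Two presets:

* `paper`: 100 epochs, batch 4, lr 1e-4 halved every 20 epochs — the
  published schedule, sized for GPU-scale data.
* `desk` (default): 25 epochs, batch 4, lr 1e-3 halved every 10 epochs,
  64×64 patches (random crops with even offsets so the subsampling cells
  stay aligned), float32 — sized for a single CPU. The scaled-down
  experiment in the acceptance suite trains 320 steps on 64 phantoms of
  64×64 px, which takes a few minutes and gains ≈ +4 dB true-clean PSNR
  over the noisy input; the ablation suite uses base_channels 16 and 384
  steps per variant.

Validation uses the pseudo-clean protocol (denoise g1, score against g2,
fixed pattern) each epoch; the best-validation-SSIM parameters are
retained. All randomness — splits, patch order, initialisation — derives
from the run seed; two runs with the same seed and data log identical
numbers.

Metrics: PSNR over the *declared* dynamic range (never per-image
min/max); SSIM with the canonical 11×11 Gaussian window (σ = 1.5,
K1 = 0.01, K2 = 0.03), cross-checked against an independent
implementation; ROI-based SNR `20·log10(mean(signal)/std(background))`
with explicit masks (phantom default: top tissue band vs. the air region
above it). Identical images report an infinite-PSNR sentinel rather than
raising.

## Numerical choices

* Orthonormal Haar convention (energy-preserving, adjoint = inverse);
  round trips are exact to ~1e-15 in float64.
* Orthonormal FFT convention pins Parseval's constant to 1, keeping
  `L_freq` comparable across resolutions.
* Bilinear upsampling uses half-pixel centres with edge clamping,
  implemented as cached separable interpolation matrices.
* Max-pool ties resolve to the first element in scan order;
  leaky-ReLU slope is 0.1; group norm uses 8 groups when divisible, else 1.
* Inference reflect-pads any input to a multiple of 16 and crops back;
  the CLI centre-crops odd-sized inputs with a warning (never silent
  padding).
* Weighted-total bookkeeping reproduces the float expression exactly
  (same association order), so the logged breakdown satisfies the
  arithmetic identity bit-for-bit.

## Known limitations

* The phantom is a structural caricature; results on it bound what the
  pipeline can do on the modelled artifact classes only.
* Stripe detection assumes stripes occupy < 25% of lines and stand ≥ 5%
  of the dynamic range above their surroundings.
* Desk-scale training (minutes on one CPU) demonstrates the learning
  dynamics, not converged performance; absolute metric values at this
  scale are far below what full-scale training on real data reaches.
* The ablation ordering is only partially reproduced on phantoms: at desk
  scale the full model outperforms the no-WSPM variant and the plain
  neighbour-subsampling baseline, but the plain-block variant with the
  full loss can exceed it in true-clean PSNR. Piecewise-constant phantoms
  contain almost no genuine high-frequency structure, so the
  detail-preserving elements of the architecture have nothing to protect
  there — preserving detail on such data means preserving speckle, and
  maximal smoothing wins. Discriminating the architecture variants in the
  published direction requires texture-rich data and longer training.
* The attention-free architecture models global structure only through
  dilated receptive fields; very long-range artifacts (full-field
  illumination gradients) are left to the notch-filter stage.
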