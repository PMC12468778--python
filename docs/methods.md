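# Methods

## Problem and model

The package addresses linear inverse imaging problems y = A x\* + w with
x\* ∈ Rⁿ a vectorized square grayscale image (n = side², row-major
vectorization throughout, intensities in [0, 1]), A ∈ R^{m×n} a known
forward operator with m ≤ n, and w ~ N(0, σ²I) additive measurement noise.
Reconstruction unrolls T iterations of a first-order scheme; every
iteration produces a pre-projection estimate x̃ᵢ from the measurements and
the iterate history, then applies a trainable DnCNN projector, either
directly (xᵢ₊₁ = P(x̃ᵢ)) or through a residual connection
(xᵢ₊₁ = x̃ᵢ + P(x̃ᵢ)).  The deep-memory scheme replaces the gradient step
with x̃ᵢ = αᵢxᵢ + Σ_{j≤i} β_{j,i} Aᵀ(y − A xⱼ): T + T(T+1)/2 trainable
scalars that strictly generalize PGD (αᵢ = 1, β_{i,i} = μ), Nesterov
acceleration (any truncated momentum schedule, shown constructively in the
tests by solving a small linear system), and AMP-style updates.

## Measurement operators

* **Gaussian**: dense i.i.d. entries N(0, 1/m), so columns have unit
  expected squared norm — the normalization AMP theory assumes.  The
  matrix is stored explicitly; σmax(A)² is estimated by 50 power
  iterations from a fixed deterministic start.
* **Undersampled DCT**: A = S·F with F the orthonormal type-II 2-D DCT
  applied matrix-free (scipy.fft) and S a row selection.  Because the rows
  are rows of an orthonormal transform, A·Aᵀ = I to float rounding at every
  sampling rate.  Two selection patterns are exposed: seeded uniform random
  rows (default) and low-frequency-first in diagonal (u+v) order; the
  appropriate pattern is application-specific, so it is a config switch
  rather than a baked-in choice.

Input SNR is reported as 10·log₁₀(mean‖Ax‖² / (mσ²)) over a test set.
This reproduces the exact −20·log₁₀(2) ≈ −6.02 dB drop per doubling of σ.
Note that for the Gaussian ensemble above E‖Ax‖² = ‖x‖² independently of
m, so this ratio decreases ≈3 dB per doubling of the sampling rate; with
the DCT operator and low-frequency selection the captured energy saturates
and the same behaviour appears.  Whether a practitioner prefers a
per-measurement or total-energy convention differs across the literature;
the definition used here is fixed and documented so numbers are
comparable across runs.

## Projector

DnCNN with an input conv (1 → width) + ReLU, L intermediate blocks of
conv (width → width) + BatchNorm + ReLU, and a single-channel output conv;
all convolutions are 3×3 with same padding, making the network
resolution-agnostic.  Defaults: width 64, L = 3, biases on every conv, BN
only in intermediate blocks.  Weight init is seeded fan-in-scaled Gaussian
(He).  The output conv is **zero-initialized** by default: a residual
projection step is then the identity at init, so the untrained unrolled
network exactly realizes the plain iterative algorithm its coefficients
encode, and training departs from a known-sound scheme instead of from a
trace scrambled by random projector output.  This is the standard trick
for residual and unrolled architectures; it can be disabled per config.

Projector weights are independent per step by default; a shared-weights
switch exists for ablation.  Parameter counts are closed-form and asserted
in the tests (1,217 for L = 0 at width 64; each block adds
9·64² + 64 + 2·64 = 37,056).

## Training

All layers and the reverse-mode sweep through the unrolled iteration are
implemented on numpy arrays in `demun.nn` — conv via im2col matrix
multiplication, standard BatchNorm train/eval semantics with running
statistics (momentum 0.1, eps 1e-5) — with every backward pass verified
against central finite differences in the test suite.  The optimizer is
Adam (lr 1e-3 default, optional per-epoch step decay), minimizing the
configured loss over measurement/image pairs generated on the fly; when
σ > 0 each batch draws fresh noise from a seeded stream, while test
measurements use one fixed seeded draw per image.  Per-image loss is the
pixel-sum of squared error, averaged over the batch; this keeps the loss
definitions literal (‖xᵢ − x*‖² per step) and the interpolation identities
exact.

Memory coefficients initialize at the PGD view with μ = 1/σmax(A)².  With
the Gaussian normalization above the gradient map I − μAᵀA has spectral
radius ≈ n/m at μ = 1, so larger initial step sizes make the T-step
forward pass blow up numerically before training can react; the spectral
step size is the classical convergent choice and any value can be forced
via `init_mu`.

Scheme-specific notes: the PGD/Nesterov baselines train a single shared
scalar μ alongside the projector weights (a per-step-μ variant is the PGD
special case of the deep-memory scheme); Nesterov uses the canonical
schedule γᵢ = (tᵢ₋₁ − 1)/tᵢ, t₀ = 1, tᵢ = (1 + √(1 + 4tᵢ₋₁²))/2.  The AMP
residual carries the Onsager correction zₜ = y − Axₜ +
(1/m)·zₜ₋₁·div(ηₜ₋₁) with the divergence estimated by a seeded
single-probe Monte-Carlo difference quotient; for end-to-end training the
correction term is treated as a constant during backpropagation
(stop-gradient), which keeps the reverse sweep simple; the forward-path
divergence estimator is validated against the closed form c·n for linear
denoisers.  Gradient histories are recomputed from stored iterates rather
than cached; the two are contractually identical and the tests compare the
one-by-one-convolution evaluation of the memory update against termwise
summation.

## Losses

Per-step squared errors eᵢ = ‖xᵢ − x*‖² combine as: last-layer (e_T),
weighted intermediate (Σ ω^(T−i) eᵢ, ω ∈ (0,1]), and skip-L (every L-th
step counting back from T, L a divisor of T).  Exact identities — skip-1 ≡
ω=1, skip-T ≡ last-layer, and the ω-gap formula — are asserted on random
traces.  The ω ablation grid {1, 0.95, 0.85, 0.75, 0.5, 0.25, 0.1, 0.01}
plus skip-5 ships as the `paper-h3` preset.

## Metrics

PSNR with peak 1.0, capped at 100 dB for zero-MSE inputs.  SSIM with the
field-standard constants (Gaussian window σ = 1.5 truncated to 11×11,
K₁ = 0.01, K₂ = 0.03, data range 1), computed with scipy filtering and
averaged over the interior (the half-window boundary ring is excluded so
the score is independent of the padding mode); agreement with
scikit-image's implementation is asserted to 1e-6.  Summary tables reduce
per-image metrics to mean ± sample standard deviation (ddof = 1).

## Synthetic data

Generators are pure functions of (kind, count, side, seed): `cartoons`
(random filled ellipses/polygons, 3–7 shapes, background 0–0.3, levels
0.2–1) exercise edges and flat regions; `grf` (power-law amplitude
spectrum |k|^(−γ), default γ = 1, min-max rescaled per image) mimic 1/f
natural-image statistics; `dct_sparse` (k random DCT coefficients, default
k = 8) are exactly sparse in the DCT domain before rescaling and make
DCT-operator recovery nearly trivial.  These stand-ins capture edge
structure and spectral decay but not texture, semantics or photometric
statistics of natural photographs, so passing toy-scale trend checks
demonstrates mechanism, not field performance.  Loaders accept PNG
directories, .npy and HDF5 stacks; RGB is converted with BT.601 luma
weights; non-square inputs are center-cropped then resized.

## Experiment harness and problem sizes

`UnrolledModel(config, train_set).fit()` returns `UnrolledResults`
(training log, `evaluate`, `summary`, HDF5+JSON checkpoints including BN
running statistics).  Every artifact embeds a 12-hex config hash;
`ablate` runs cross-product grids, caches finished cells by hash, and
survives single-cell failures.

The built-in direction study (`hypothesis_direction_study`) uses side 16,
T = 5, L = 3, width 24, sampling rate 0.3, 200 training / 64 test
cartoons, 12 epochs, batch 16, three seeds — sizes chosen so the full
study runs in minutes on one CPU.  T sits at the upper end of the small-T
band because the intermediate-supervision and residual-connection effects
need unrolling depth to act on.  The study compares last-layer vs
unweighted intermediate loss, direct vs residual projections, and the
trained network vs the Aᵀy baseline, reporting per-seed wins: at this
scale these are direction checks; magnitudes at full scale (50×50 images,
T = 30, thousands of training images, GPU-scale optimization) are outside
what desk-scale training can reproduce.

## Known limitations

* Real-valued operators only: no complex k-space, coil maps, or Radon
  projectors.
* AMP training uses the stop-gradient Onsager approximation; AMP theory
  itself assumes Gaussian A (a warning is emitted otherwise).
* BatchNorm makes training-mode outputs batch-composition-dependent;
  evaluation always uses running statistics.
* The numpy training loop is single-threaded BLAS-bound and intended for
  desk-scale studies, not production training.
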