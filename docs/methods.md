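# Methods

## Problem setting

Compact portable ultrasound probes trade image quality for cost and size.
Given pairs of B-mode images of the same anatomy acquired by a low-end and a
high-end device — anatomically paired but *not* pixel-registered, because the
two sweeps happen at different times and orientations — the goal is a mapping
that takes a low-quality frame to an image with the appearance of the
high-end device while preserving the underlying anatomy.

## Model

The framework is a cycle-consistent adversarial translator between the
low-quality domain L and the high-quality domain H:

- **Generators.** `G_H : L → H` and `G_L : H → L` share one UNet
  architecture and never share parameters. The encoder is a stack of
  4-wide stride-2 convolutions; the first stage emits `base_channels`
  (default 64) and widths double per stage, capped at `8 × base_channels`.
  Encoder stages use instance normalization and leaky ReLU (slope 0.2); the
  first stage and the 1×1 bottleneck carry no normalization. The decoder
  mirrors the encoder with stride-2 transposed convolutions, instance
  normalization and ReLU, concatenating each encoder stage's output to its
  mirror (skip connections). Dropout (rate 0.5) sits on the configured deep
  decoder stages — the three innermost by default. A final transposed
  convolution with tanh maps to one channel in [−1, 1]. Depth is
  configurable: depth 8 suits 256-pixel inputs, depth 6 the 64-pixel desk
  scale; the input side must be divisible by 2^depth.

- **Discriminators.** `D_H` and `D_L` are patch critics: five 4-wide
  convolutions (strides 2,2,2,1,1, padding 1, leaky ReLU 0.2 between), all
  spectrally normalized, ending in a 1-channel score map — 30×30 for a
  256-pixel input — so realism is judged per overlapping patch rather than
  per image. Spectral normalization divides each weight by its largest
  singular value, estimated by persistent power iteration (one step per
  training iteration; iterated to convergence in verification mode), keeping
  every layer 1-Lipschitz. The discriminator uses no other normalization.

- **Initialization.** All weights are zero-mean Gaussian, std 0.02, from a
  seeded generator; biases start at zero.

## Losses

With batches `L`, `H` and fakes `H' = G_H(L)`, `L' = G_L(H)`:

- **Adversarial** (least-squares): `MSE(D_H(H'), 1) + MSE(D_L(L'), 1)`.
  The all-ones target is materialized at the score-map shape.
- **Cycle consistency:** `|G_L(H') − L|₁ + |G_H(L') − H|₁`.
- **Paired L1:** `|H' − H|₁ + |L' − L|₁`. Both translation directions are
  included by default; a flag restricts it to the enhancement direction.
- **Perceptual distance:** images pass through a frozen convolutional
  feature extractor; at each stage the feature vectors are unit-normalized
  over channels at every spatial position, squared differences are summed
  over channels, averaged over space and batch, weighted per stage
  (weights default to 1) and summed over stages. The default backbone is a
  five-stage random convolutional stack with He-scaled weights from a fixed
  seed — random deep features give a usable multi-scale perceptual
  substrate and keep the package free of downloads; any extractor with the
  same interface (e.g. pretrained stages supplied as arrays) can be plugged
  in.

The aggregate generator objective weights the four terms with
λ_adv = 1, λ_cycle = 10, λ_L1 = 2, λ_per = 10.

- **Discriminator objective with conditional label smoothing:** each
  discriminator scores a real batch and a detached fake batch and minimizes
  `MSE(real, label) + MSE(fake, 0)`. The real-image label is 1.0 while both
  batch-mean scores stay strictly below 0.9; once either mean reaches 0.9
  the label drops to 0.9, discouraging overconfidence. The rule is applied
  per discriminator from that step's own score means.

All reductions are means over batch, channels and space, so the λ weights
are independent of batch size. No identity/self-regularization term and no
historical fake pool are used.

## Training procedure

Per step: one joint update of both generators on the aggregate loss, then
one update of each discriminator on detached fakes. Optimization is Adam
(β₁ = 0.9, β₂ = 0.999), initial learning rate 3×10⁻⁴, halved every 100
epochs; reference schedule 300 epochs at batch 4. The dataset is split
70/10/20 into train/validation/test (floor sizes for validation and test,
remainder to training, seeded shuffle). The `mixed_precision` flag applies
static loss scaling (scale before backward, unscale before the update) —
numerically neutral in the float32 compute core, retained as the gradient
scaling stage of the procedure. The best checkpoint is selected by
validation PSNR (configurable); latest and best checkpoints store all four
parameter sets, both architecture specs, optimizer state, epoch and seed.

The compute core is a reverse-mode automatic-differentiation engine over
NumPy arrays written for this package (strided and transposed convolution
via im2col/col2im, instance normalization, activations, reductions), with
gradients verified against central finite differences in the test suite.

## Synthetic phantoms

The paired-image generator emulates the *statistical* structure the
framework assumes, not anatomy:

- The clean scene is a piecewise-elliptical echogenicity map: uniform
  background (default 0.35) with `n_inclusions` random ellipses of distinct
  reflectivity — the first-order B-mode scene model.
- Speckle is multiplicative gamma noise with shape `looks` and unit mean
  (variance 1/looks): the high-quality member uses 4 looks.
- The low-quality member is derived from the high-quality member by, in
  order: a smooth random warp (Gaussian-filtered displacement field scaled
  to a peak amplitude, default 1 px — the pre-acquisition scene change that
  makes real pairs nonregistered), Gaussian blur (default σ = 2 px),
  block-mean downsampling and nearest-neighbor re-expansion (default ×2),
  gamma dynamic-range compression (default exponent 1.5), and re-speckling
  at 2 looks (sensor-level noise is applied last). Values outside [0, 1]
  are clipped, not rescaled, so echogenicity stays comparable across pairs.
- A pair is flagged `registered` exactly when the warp amplitude is zero.

What the phantoms do **not** model: organ-specific anatomy, attenuation and
shadowing, depth-dependent resolution, probe-specific post-processing.
Passing desk-scale tests therefore demonstrates that the training loop
extracts a genuine enhancement signal under speckled, warped, contrast-
compressed degradations — not that clinical image quality is reproduced.

## Evaluation metrics

All metrics run on unit-interval images (MAX_I = 1), making PSNR invariant
to the source bit depth.

- **SSI** — windowed by default (11×11 Gaussian window, σ = 1.5, the
  standard structural-similarity formulation, computed via scikit-image);
  the single whole-image-moment form is available as `global` mode.
  Stabilizers C₁ = (0.01 MAX_I)², C₂ = (0.03 MAX_I)².
- **LNCC** — mean over all sliding 9×9 windows (reflect padding) of the
  local Pearson correlation, with 10⁻⁸ in the denominator; clipped to
  [−1, 1].
- **PSNR** — `10 log₁₀(MAX_I²/MSE)`; identical images report +∞ in per-pair
  tables and are capped at 100 dB inside aggregate means (flagged).
- **Perceptual distance** — the training-time feature distance applied to
  single pairs after mapping [0, 1] → [−1, 1]; lower is better.

Model comparisons use the one-sided Wilcoxon signed-rank test on per-pair
scores (exact distribution at small n without ties, normal approximation
otherwise; higher-better orientation for SSI/LNCC/PSNR, lower-better for
the perceptual distance). All-zero differences are reported as undefined
(NaN) with a warning.

## Desk-scale benchmark configuration

`echogan.benchmark.desk_scale_experiment` runs the full loop at problem
sizes chosen for a single CPU: 200 pairs of 64-pixel phantoms (blur σ = 2,
×2 downsampling, speckle 4 → 2 looks, 1 px warp), depth-6 generators and
discriminators at width 24, the random-conv perceptual backbone, 10 epochs
at batch 4, evaluated on the 40-pair held-out split against the unenhanced
reference-low baseline. Two choices depart from the reference training
configuration, both consequences of the 30-fold shorter schedule: the
initial learning rate is 2×10⁻³ (a proportionally larger step for a
compressed schedule), and decoder dropout is disabled (a regularizer for
300-epoch training is counterproductive in a 10-epoch underfitting regime).
λ weights, optimizer, batch size, split fractions and the degradation
parameters are the reference values.

## Numerical choices and degenerate inputs

- Channel normalization in the perceptual distance adds 10⁻¹⁰ inside the
  square root; exactly-zero feature vectors therefore map to zero.
- All-zero weights cannot be spectrally normalized (σ undefined); they are
  returned unchanged and a warning is logged.
- Power iteration runs one step per training forward with persistent
  vectors; verification paths iterate until the σ estimate stabilizes
  (relative tolerance 10⁻⁸, capped at 500 iterations), which guards against
  slow convergence when the top singular values are close.
- Dropout draws from a per-model seeded stream, so a fixed model seed
  reproduces an entire training run bit-for-bit on one machine.
- `total_generator_loss` refuses non-finite components by name; a
  non-finite step loss aborts the step with the offending term.

## Known limitations

- Random-feature perceptual distances are less aligned with human judgment
  than learned-weight backbones; conclusions about perceptual quality on
  real clinical data require a pretrained extractor.
- The NumPy compute core targets correctness and reproducibility, not
  throughput; reference-scale (256 px, 300 epoch) training is out of its
  intended range.
- Phantom parameters are free knobs, not calibrated to any specific device
  pair.
- The warp model displaces the scene smoothly but does not change view
  geometry; real probe repositioning can expose different anatomy.
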