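# Methods

This note records the models, parameters, and numerical choices implemented
in `ramanblend`, and the limitations of each.

## Data model

A dataset is a dense matrix of intensities (rows = spectra, columns =
wavenumber positions on a shared axis) with binary labels (1 = positive
class) and a provenance tag per row (`real`, `blend`, or `vae`). CSV
round-trips write intensities at 9 significant digits; equality, content
fingerprints, and reproducibility guarantees are all defined at that
precision.

## Simulator

Spectra are sums of Gaussian and/or Lorentzian peaks on a low-order
polynomial baseline, with multiplicative per-peak amplitude jitter and
additive white Gaussian detector noise. Class identity enters only through
class-specific peaks; shared peaks and the baseline are common to both
classes. Label counts follow the configured positive prior exactly, rounded
half-up toward the positive class. Two profiles are provided:

* `chlorinated`: 2473 features over 350–3500 cm⁻¹, positive prior 0.67,
  class-informative peaks below ~1170 cm⁻¹, intensities natively in [0, 1].
* `sars`: 900 features (configurable) over 600–1800 cm⁻¹, positive prior
  0.51, an affine rescale to roughly [−0.1, 0.4] and eight dead (all-zero)
  edge columns, so preprocessing is genuinely exercised.

**Realism.** The simulator reproduces the *structural* properties that the
pipeline depends on — peak shapes, baselines, noise, class overlap, dead
detector columns, out-of-range intensities — not calibrated Raman
cross-sections, instrument response, or cosmic-ray artifacts. Quantitative
results on simulated data characterize the pipeline, not any real assay.

## Preprocessing

All-zero feature columns are removed first; if any remaining intensity lies
outside [0, 1], a single global min–max transform
`(x − min) / (max − min)` is applied over the whole matrix (not per
spectrum or per column), preserving relative peak heights across spectra.
Data already in [0, 1] pass through unchanged. Normalization parameters are
recorded so holdout data receive the training transform.

## Inverted stratified 3-fold cross-validation

Within each class, indices are shuffled with a seeded generator and cut into
`k` contiguous chunks; `count mod k` spectra per class are dropped from
training and placed in **every** holdout. Each fold trains on one chunk per
class (one third of the data) and evaluates on the complement (two thirds),
so training folds are deliberately scarce. With 159/150 labels this yields
103-spectrum training folds and 206-spectrum holdouts; with 154/76 labels,
one spectrum per class is dropped and folds are 51/25 train versus 154
holdout. Folds are persisted as CSVs plus a JSON manifest (seed, k, indices),
and experiments consume only the persisted folds.

## Weighted blending

For each class, every unordered parent pair (A, B) and every weight
`w ∈ {0.1, …, 0.9}` produces `w·A + (1 − w)·B`. Counts are exactly
`|θ|·N(N−1)/2` per class (14 175 for a 51/25 fold, 23 427 for 53/50). Row
order is deterministic: class 0 before class 1, pairs in lexicographic index
order, weights ascending. Blends are convex, hence bounded by the parents
pointwise and closed on [0, 1]; they can only interpolate, never
extrapolate, the training distribution.

## Variational autoencoder

Encoder: two dense ELU layers of 500 units, then two linear heads giving the
latent mean `μ` and `γ = log σ` (50 dimensions). Decoder mirrors the encoder
and ends in a sigmoid. Sampling uses the reparameterization
`z = μ + ε ⊙ e^γ`, `ε ∼ N(0, I)`. The loss is the summed Bernoulli
cross-entropy reconstruction term plus the closed-form KL divergence
`−½ Σ (1 + 2γ − μ² − e^{2γ})`, optimized with Adam at learning rate 0.001.
The headline schedule is 10 000 epochs; mini-batch size 32 is an
implementation choice. Inputs must lie in [0, 1] (enforced), as the
Bernoulli likelihood is otherwise ill-defined. Generation is
class-conditional by construction: a real spectrum of the requested class is
drawn (with replacement), encoded, its posterior sampled, and decoded; the
synthetic spectrum inherits the source label.

## Classifiers

Both models are binary classifiers ending in a single sigmoid unit and are
trained with Adam (learning rate 10⁻⁴), batch size 1, binary cross-entropy,
100 epochs at full scale, across seeds 0–4.

* **CNN**: two blocks of (valid 1-D convolution, kernel 5 — 32 filters then
  64 — ReLU, non-overlapping max-pool of 2, dropout 0.5), flatten, a dense
  layer of 1024 ReLU units whose input width is set by the flattened
  convolutional output, a second dense 1024-unit ReLU layer, then the
  sigmoid output. Reading the first dense layer's *width* as the flattened
  size itself would give ~1.5 × 10⁹ parameters at 2473 input features, which
  is infeasible on modest hardware; the implemented reading (flattened size
  determines the layer's input, width 1024) keeps the two architectures
  parallel.
* **FCNN**: dense D→D ReLU, dense D→1024 ReLU, dense 1024→1, for
  `D² + D + 1024·D + 1024 + 1024 + 1` parameters at D input features.

Weights are initialized from a truncated normal (mean 0, σ = 0.1, clipped at
±2σ) with biases at 0.1. Dropout uses inverted scaling and is disabled at
inference, so prediction is deterministic.

## Numerical choices

* The networks are implemented directly on numpy (manual backpropagation;
  convolution via stride tricks). No GPU framework is required; the cost is
  speed — batch-size-1 training is O(dataset × epochs) Adam updates, so
  full-scale runs take hours of CPU time.
* All cross-entropies are computed on logits via
  `softplus(z) − x·z`, never on probabilities, avoiding `log(0)`.
* Ties in prior-preserving rounding go toward the positive class
  (round-half-up).
* Standard deviations in result tables are population standard deviations
  (ddof = 0) over seeds × folds.
* The discrete Fréchet distance uses the standard dynamic program
  `ca(i,j) = max(d(pᵢ,qⱼ), min(ca(i−1,j), ca(i−1,j−1), ca(i,j−1)))`,
  implemented iteratively; mean spectra can be paired with their feature
  index, their wavenumber, or compared as y-only sequences (`x_mode`).
  The test suite checks the DP against brute-force enumeration of all
  monotone couplings.
* PCA scores come from a full-SVD scikit-learn PCA with a deterministic sign
  convention (largest-magnitude loading positive).
* A leakage guard fingerprints (SHA-256 at CSV precision) the training fold
  that produced each synthetic pool; augmentation refuses pools whose
  fingerprint or fold index does not match.

## Limitations

* Simulated data are far more separable than real assays; balanced
  accuracies reported on them say nothing about real-world performance and
  should only be used to verify pipeline mechanics and trends.
* Blending cannot generate variance outside the convex hull of the training
  fold; the VAE can, but at short training it produces over-smoothed
  spectra. Neither generator models peak-position drift or instrument
  effects.
* The VAE loss uses `γ = log σ`; a `log σ²` convention would rescale the KL
  term but not change the pipeline's structure.
* Exact kernel/pool/dropout values for the convolutional reference
  architecture are declared defaults, not fitted or tuned; no
  hyperparameter search is performed anywhere (by design).
* Full-scale settings (10 000 VAE epochs; 100 epochs × batch size 1 × 15
  runs per table cell) are computationally heavy on CPU; the shipped tests
  and examples use scaled-down sizes and epochs throughout.
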