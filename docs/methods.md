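# Methods

This document records the modeling and numerical choices behind
`pixelmd`, in enough detail to re-derive every number the package
produces.

## Pixel-map encoding

A frame of an ensemble with `A` atoms becomes an `S×S×3` uint8 image
with `S = ceil(sqrt(A))`. Atom `k` (in topology order) occupies
row-major pixel `k`; the remaining `S²−A` pixels are black padding.
Channels are the min-max normalized coordinates:

```
R,G,B = round(255 · (x,y,z − min) / (max − min))
```

with **round-half-up** (`floor(v + 0.5)`) so that the midpoint maps
deterministically to 128. The per-axis `min`/`max` are fitted **globally
over every frame of both states**; per-frame normalization would erase
the inter-state geometric differences the classifier must learn.
Out-of-bounds coordinates (possible when encoding new frames under
previously fitted bounds) are clipped and counted. Decoding inverts the
map to within half a quantization step, `(max−min)/510` per axis.

Ensembles are rigid-body superposed (Kabsch) onto a common reference
before encoding so that pixel intensities reflect internal conformation,
not diffusion.

## CNN classifier

Architecture (input `S×S×3`):

| layer | shape |
|---|---|
| conv 3×3, 32 filters, ReLU | same padding |
| conv 3×3, 32 filters, ReLU | same padding |
| max-pool 2×2 + dropout 0.25 | |
| conv 3×3, 64 filters, ReLU | same padding |
| conv 3×3, 64 filters, ReLU | same padding |
| max-pool 2×2 + dropout 0.25 | |
| dense 512, ReLU + dropout 0.5 | |
| dense 2, softmax | |

Loss is categorical cross-entropy, optimized with Adam (lr 1e-3, batch
32). Implementation is pure numpy: im2col convolutions via
`sliding_window_view`, the backward pass of the convolution as a full
convolution with flipped transposed kernels, tie-splitting max-pool
gradients, inverted dropout.

**Input standardization.** Images are standardized inside the network
(per-pixel mean over the training set, one global standard deviation);
the statistics are stored with the weights and applied at prediction.
This is not cosmetic: with raw `x/255` inputs, training on small
datasets plateaus at chance for tens of epochs before escaping; with
standardized inputs it converges in 2–3 epochs.

**Early stopping.** A seeded 10% validation split monitors training.
Training stops when the validation loss fails to improve for
`patience` epochs (best epoch restored), or when it stays below
`convergence_loss` (default 1e-2) for **two consecutive epochs** — a
single small validation evaluation is too noisy a convergence signal.

## Cross-validation

MD frames are strongly autocorrelated, so random splits leak
information. Each trajectory is cut into 10 contiguous chronological
groups; each group into 5 contiguous sub-blocks (remainders appended to
the last block); fold `k` validates on sub-block `k` of every group of
every trajectory. Validation frames therefore interleave chronologically
with training frames without being their immediate neighbors' duplicates,
and every frame is validated exactly once across the five folds.
Per-fold accuracy is

```
accuracy = (TP + TN) / (TP + TN + FP + FN)
```

with the lexicographically second class label taken as positive. Each
fold trains from a fresh seeded initialization (`seed·1_000_003 + fold`).

## Local surrogate explanations

For each explained conformation (a stratified sample of `n_per_state`
frames per state):

1. Generate 1,000 perturbed images by masking each non-padding pixel
   independently with probability 0.5; masked pixels take the
   **dataset-mean** pixel value. Masking to black would alias
   perturbation with padding, which is black by construction. One
   unperturbed anchor row is kept.
2. Query the CNN for the probability of the frame's own state.
3. Fit a weighted linear model (intercept + one slope per pixel) by
   weighted least squares with proximity weights `exp(−d²/σ²)`, where
   `d` is the Euclidean distance between the binary keep/mask vector and
   the all-ones original and `σ = 0.75·√P` (`P` = non-padding pixels).
   Distances are measured in the binary presence space — the convention
   of image-mode LIME — because intensity-space distances under this σ
   would give all perturbations near-zero weight. A tiny ridge (1e-8)
   stabilizes the normal equations; a rank-deficient design falls back
   to a larger penalty with a warning.
4. Binarize: the top 10% of pixels by |coefficient| score 1, the rest 0
   (ties break to the lower pixel index).
5. Aggregate: residue score = mean of its atoms' binary scores over all
   explained conformations; report the top-K residues (K = 50 at full
   scale), ties again to the lower residue index.

Because pixel `k` is atom `k`, no heuristic segmentation step is needed;
the surrogate's features are exactly atoms.

## Ensemble analyses

* **RMSD series** — per-frame least-squares RMSD to a reference over a
  selection, with optional Kabsch superposition per frame.
* **Pair distances** — Cα–Cα or closest-heavy-atom distance per frame;
  a contact is a distance below 4.5 Å (strict inequality).
* **DCCM** — `C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)` over Cα
  displacement fluctuations about the time-mean position. Immobile
  residues produce NaN rows (undefined, not zero) with a warning. The
  ensemble must be aligned first or rigid-body motion leaks in.
* **PCA** — eigendecomposition of the 3R×3R coordinate covariance of the
  aligned ensemble; PC1 per-residue displacement vectors are the leading
  eigenvector's 3-vector components scaled by √λ₁.
* **State space** — normalized 2D histogram over (RMSD, interdomain
  distance), optionally with 2-means cluster labels.
* **Crystal-pair displacement** — superpose structure B on structure A
  over the Cα atoms of shared alignment residues, then report the
  Cα–Cα distance of the residue of interest.

## Synthetic generator

The generator exists to give every analysis a planted ground truth:

* **Reference chain** — self-avoiding Cα random walk (3.8 Å steps,
  direction persistence 0.8, non-consecutive clearance > 4.0 Å);
  optionally `atoms_per_residue − 1` satellite heavy atoms per residue.
* **Two states** — identical fluctuation model; the *active* state
  shifts the mean position of the planted discriminative residues by
  `mean_shift` Å in seeded random directions. Defaults pick
  `min(10, n/2)` evenly spaced residues.
* **Correlation blocks** — residues of two ranges share a latent factor
  with loading √ρ, giving exact pairwise cross-correlation ρ (PSD by
  construction for one block; overlapping blocks are repaired to the
  nearest PSD matrix with a warning).
* **Interdomain pair** — the second domain translates rigidly; stable in
  the inactive state (N(5, 0.3) Å), telegraph-switching between closed
  (~5 Å) and open (~25 Å) in the active state (switch probability 0.05
  per frame).
* **Determinism** — all randomness flows from
  `default_rng([seed, stream, trajectory])`; the same spec and seed
  reproduce bit-identical ensembles.

## Problem sizes

The package's reference benchmark (`scripts/acceptance.py`) uses 3
trajectories per state × 1,000 frames, 100 residues × 10 atoms
(→ 32×32 maps), 10 discriminative residues, 3 Å shift over 0.5 Å noise.
Tests use smaller instances of the same generator (Cα-only, 10×10 maps)
so the full suite runs on one CPU in well under the CI budget.

## Limitations

* The CNN is a faithful but compact numpy implementation; it is not
  optimized for GPU-scale data and trains at roughly 10³ images/minute
  at 32×32 on one CPU core.
* Surrogate explanations are local and linear: coefficients rank pixels
  by local influence on the queried probability; they do not constitute
  a global feature attribution, and binarization discards magnitude
  information by design (only ranks survive).
* Pixel-map reconstruction is lossy (uint8 quantization), bounded by
  half a quantization step per axis.
* The crystal-structure displacement benchmark requires experimental
  PDB files which must be supplied locally; no network access is
  assumed anywhere in the package.
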