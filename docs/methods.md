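# Methods

This note documents the models, procedures, parameter choices and known
limitations of `sanityscan`.  It states no empirical numbers beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## 1. Problem setting

Weakly supervised volumetric classification: each patient contributes one
CT volume (Hounsfield units, per-axis physical spacing), a binary
segmentation mask of the target region (organ ± lesion), and one binary
label.  The question the package answers is not "how accurate is the
classifier" but "is its accuracy attributable to the target" — a
pre-validation reliability check.  The three sanity tests (target
ablation, noise images, ROI sensitivity) operationalize the idea that a
sound model's performance must collapse when the causal signal is removed
and must be stable when only irrelevant context changes.

## 2. Preprocessing chain

Order: resample → resize → clip → normalize.

* **Isotropic resampling** to 1.0 mm via separable windowed-sinc
  interpolation (Lanczos window, radius a = 3).  Implemented as per-axis
  interpolation matrices with pixel-center alignment, edge clamping and
  row renormalization, so constants are reproduced exactly and the
  physical extent is preserved to within one voxel per axis.  The matrix
  formulation is audited against a brute-force 1-D windowed-sinc oracle
  in the tests and is orders of magnitude faster than generic resamplers
  at this problem size.
* **Slice resize** to 299 × 299 (the standard input size of the CNN
  families these pipelines use) with bilinear interpolation.  Non-square
  fields of view are stretched, not padded; recipes of this family fix
  only the output size, and the distortion choice is recorded as a
  config-level decision (`resize_slices` is aspect-ratio agnostic).
* **HU clipping** to ±300 HU (soft-tissue window).
* **Normalization**: z-score with mean/std pooled over *training* voxels
  only.  The "[0, 1]" phrasing sometimes attached to such recipes is
  inconsistent with a z-score; the operational subtract-mean /
  divide-by-std definition is implemented.

Masks are resampled with nearest-neighbour interpolation and
re-binarized.

## 3. Input formats

* `wp` — preprocess(volume).
* `wop` — target voxels set to 0 HU (water) *in the HU domain, before
  preprocessing*, then the same chain.  Zeroing first keeps one canonical
  pipeline order; the interpolation halo around the mask is bounded and
  quantified in tests.
* `target` — per-slice axis-aligned bounding box of the mask (computed on
  the isotropic grid), out-of-mask voxels inside the box zeroed, box
  resized to 299 × 299; slices that do not intersect the mask are
  dropped.  A fixed-box variant is a configuration option; per-slice
  boxes are the default because the tight crop is the point of the
  format.
* `noise` — see §4.

## 4. Noise images

For s slices: s − 1 adjacent-slice differences D_t = I_t − I_{t−1}
(shared anatomy cancels); per difference image a Sobel gradient magnitude
map flags residual structure (pixels above the 0.90 quantile of the
image's own magnitudes; patches with more than 10% flagged pixels are
excluded — the quantile rule avoids a fixed HU-scale threshold);
non-overlapping 30 × 30 patches anchored top-left, remainders discarded
(a 299 × 299 image yields 81 candidates); patches whose value histogram
looks like homogeneous noise are kept: |skewness| ≤ 0.1, Pearson
(non-excess) kurtosis within 3.0 ± 0.5, sample SD < 16 (on the HU
difference scale; rescale by the training SD if run on z-scored input),
and a single histogram peak.  Peak counting uses Freedman–Diaconis bins,
a 3-bin moving average, and counts strict local maxima above 5% of the
modal count — the underlying recipe leaves binning unspecified, so these
are exposed as configuration.  Selected patches are averaged into one
30 × 30 noise image and upsampled to 299 × 299 with the same windowed
sinc.  If no patch qualifies, the minimum-Sobel-energy patch substitutes
(logged), keeping the s − 1 output cardinality the aggregation head
expects.  Noise generation runs after clipping and before normalization
(the procedure is defined on the HU scans); a config switch allows the
normalized variant.

## 5. Classifier

Slice embeddings h_t feed one hidden ReLU layer (h = 20 units), mean
pooling over slices, and a logistic output:
σ(b + (1/s)·wᵀ Σ_t ReLU(U h_t + a)).  Mean pooling makes the score
invariant to slice order and count duplication.  Training: binary
cross-entropy, classic (coupled) Adam with L2 decay on U and w only
(lr 1e-4, decay 1e-6, β₁ = 0.9, β₂ = 0.999, bias-corrected moments),
batch size 1, 100 epochs, Kaiming fan-in initialization for U and w with
zero biases, and tune-loss plateau halving (patience 5 epochs, minimum
improvement 1e-4, floor 1e-6 — the halving factor is prescribed, the
patience is a package choice).  Gradients are analytic and validated
against central finite differences.

### Built-in slice embedder

A pretrained CNN is deliberately out of scope; the built-in
`RadiomicSliceExtractor` computes a deterministic 24-value descriptor
block per region:

* affine sub-block (8): mean, SD, and the 5/25/50/75/95/99th percentiles
  of the raw values;
* invariant sub-block (16): skewness, kurtosis, gradient-magnitude
  mean/SD, row/column gradient anisotropy, lag-1 spatial autocorrelations
  (row, col), 8 log-spaced ring-averaged spectral power fractions
  (computed on the largest centered power-of-two window — 256 px of a
  299 px slice), and the z-value histogram entropy.  All invariant
  descriptors are computed on the z-scored region.

The block is computed for each cell of a 3 × 3 partition of the slice;
per-cell values are pooled across cells with max, median and min, and
the embedding is [cell-max, cell-median, cell-min] (72 base features; a
whole-slice block can be prepended with ``include_global``).  The
pooling mirrors a convolutional encoder's spatial pooling and matters
for two reasons: the cell-max responds to a compact structure wherever
it sits (translation robustness — a lesion moves between patients), and
the cell-median is insensitive to edits confined to a minority of
cells, which is what lets a model trained on full volumes carry
background-texture knowledge over to target-removed volumes.  Purely
global descriptors entangle target and background (no cross-format
transfer); purely per-cell descriptors lose translation robustness.
With a 299 px slice, each cell is 99 px and its spectral window 64 px,
so the cells resolve spatial frequencies down to ~0.016 cycles/pixel;
the lag-1 autocorrelations carry the smoother, lower-frequency texture
content.

The emitted embedding is the pooled descriptor vector passed through a
fixed, seeded random linear expansion to d = 256.  The expansion adds no
information; it restores the embedding-width regime the fixed Adam recipe
is calibrated for — with per-parameter Adam steps, the attainable logit
displacement in a fixed epoch budget grows with width, and a ~100-wide
input starves the optimizer (observed as underfitting on perfectly
separable cohorts).  Log-spaced spectral bands matter because noise
texture differences concentrate at low spatial frequency, especially
after the 30 → 299 upsampling of noise images compresses all patch-scale
structure below ~0.05 cycles/pixel.

In the evaluation harness, the per-fold feature standardization acts on
the base descriptors *before* the expansion.  Order matters: expanding
raw-scale descriptors lets HU-scale features (hundreds) dominate every
mixed coordinate, burying the small texture statistics (~0.01–1) beyond
what post-expansion standardization can recover; standardizing first
gives every descriptor a comparable voice in the mixture.

Because every invariant descriptor is unchanged by a global affine
intensity map and the affine sub-blocks transform in closed form
(pooling commutes with monotone affine maps), embeddings of a z-scored
volume are an exact function of embeddings of the raw volume
(`shift_scale`); the harness exploits this to avoid re-extracting per
fold, and an equivalence test pins the two routes together.  External
CNN extractors plug in through the same interface (for grayscale CT,
slices are replicated to faux-RGB by the adapter, not in the core).

## 6. Evaluation statistics

* **Folds**: stratified 5-fold at patient level (scikit-learn), per-fold
  class counts within one of perfect stratification.
* **AUC**: Mann–Whitney with midrank ties (rank formula; cross-checked
  against an exhaustive pair-count oracle and scikit-learn).
* **cvAUC CI**: the point estimate is the fold-size-weighted mean of fold
  AUCs; the variance pools per-observation influence functions within
  folds — IC = (F₀(x) − AUC)/p₁ for positives and (S₁(x) − AUC)/p₀ for
  negatives, Var = mean_k σ̂²_k / n — with a Wald interval truncated to
  [0, 1].  Calibration is verified by simulation (binormal scores, true
  AUC 0.75, 1,000 replicates) rather than against an external package;
  the plain Wald interval undercovers mildly at small n, which the
  acceptance band accounts for.
* **DeLong**: paired test from structural components V10/V01 (midrank
  form), covariance with ddof = 1, two-sided normal p.  Identical score
  vectors return z = 0, p = 1 by contract.  Across CV, DeLong runs on
  pooled out-of-fold scores.
* **Cross-format matrix**: per fold, each training-format model is fit on
  the in-fold patients (with a stratified 20% tuning subset for the
  plateau scheduler) and scored on held-out patients rendered in every
  test format.  Normalization statistics are pooled over the training
  patients of the fold, per format; held-out data is rendered with its
  own format's training statistics.  Embeddings are standardized per
  feature with training-fold statistics as part of each model's input
  pipeline and that standardizer is applied to whatever test rendering
  the model is fed.  No patient ever appears on both sides of a cell.

## 7. Sanity-test decisions

Tests 1–2 pass iff the relevant cell's 95% CI contains 0.5 — "around
0.5" with a cohort-size-adaptive band; an AUC significantly *below* 0.5
also fails (anti-learning is still confounding).  Test 3 compares the
`target` self-test against the `target`-trained model on `wp` renderings
with a paired DeLong test at α = 0.05; the compared pair is configurable
because other pairings are defensible.  Decisions are pure functions of
(matrix, criteria); the report carries seeds and a config hash.

## 8. Synthetic phantoms

Each phantom is a thin axial slab: 10 native slices of 128 × 128 at
1.25 × 1.0 × 1.0 mm (12 slices after 1 mm resampling), an in-plane
elliptical organ (HU 60 ± 12 per patient, radii ≈ 16 × 12 px — about 2%
of the field of view, the pancreas-to-image ratio of a real abdominal
scan), a soft-tissue background (−80 HU ± 8 per patient), six
class-independent clutter blobs (±10–30 HU, soft edges) standing in for
surrounding anatomy, and — for positives — a focal lesion inside the
organ (radius 6 px, contrast +40 HU ± 40% per patient).  Tissue noise is
Gaussian, SD 14 HU, independent per voxel; with a texture confound the
in-plane spectrum is shaped as f^(−β) with β per class.  Further
confound injectors: a global per-class HU offset and per-class in-plane
Gaussian smoothing.  All structure is constant along the slice axis, and
the anatomy image is smoothed in-plane (σ 0.8 px) before noise is
added.

Design rationale, in the package's own words:

* **Thin-slab (z-constant) anatomy.**  Adjacent-slice subtraction assumes
  anatomy varies slowly across neighbouring slices.  With z-varying
  synthetic structures, the slice-to-slice increments of the *lesion*
  survive differencing, pass the uniformity filter (which checks shape,
  spread and modality but not mean offsets), and leak class signal into
  supposedly anatomy-free noise images — the confound-free chance-level
  expectation then fails for a reason that is an artifact of the phantom,
  not of the method.  Making the slab z-constant realizes the method's
  own regime exactly: differences contain only noise.
* **Lesion contrast and per-patient variability.**  The lesion is
  deliberately a *good but imperfect* signal at the cohort sizes used
  (organ enhancement and lesion contrast jitter patient-to-patient).  A
  perfectly separable target lets the optimizer zero the loss without
  touching any covariate, in which case an injected confound is
  (correctly) not exploited and the ablation test passes; the regime the
  sanity tests target is the one where the causal signal is hard enough
  that shortcuts compete.
* **Small organ.**  Target removal must be a small edit relative to the
  image, as it is for a real organ mask; when a phantom organ covers a
  large image fraction, removal pushes the whole embedding out of the
  training distribution and no classifier — sound or confounded —
  transfers, which voids the ablation test's premise.
* **Clutter.**  On perfectly uniform backgrounds, the count of qualifying
  noise patches becomes an informative statistic of its own; clutter
  makes counts and local statistics vary patient-to-patient as they do in
  real scans.
* **Per-patient seeds** are spawned from the cohort seed
  (`SeedSequence.spawn`), so any single phantom is reproducible in
  isolation; the random stream is consumed identically for both labels,
  making paired class comparisons exact.

What the phantoms do *not* model: physical CT projection/reconstruction,
beam hardening, metal or motion artifacts, anatomic variability beyond
geometric jitter, z-correlated noise.  Passing the suite on phantoms
shows the pipeline's logic and statistics behave as designed under known
generative structure; it does not certify behavior on any real scanner's
data.

## 9. Problem sizes and defaults

Replicated experiments use 30 patients per class, 5 folds, and 20 cohort
seeds per condition; phantom geometry is as above.  These sizes were
chosen so the full acceptance recomputation runs in minutes on a single
CPU while the fold AUC intervals remain wide enough to behave like the
small-cohort clinical setting the method targets.  All of them are
ordinary function parameters, not constants.

## 10. Known limitations

* The influence-curve Wald interval is mildly anticonservative for
  extreme AUCs and small folds; near-1.0 cells report degenerate [1, 1]
  intervals.
* The DeLong normal approximation is asymptotic; with fewer than ~20
  patients, p-values are coarse.
* The built-in embedder is a texture/intensity descriptor bank: it makes
  intensity and noise-texture confounds learnable by design, but it
  cannot represent shape or anatomy the way a CNN does, so phantom
  results do not bound CNN behavior on real data.
* Noise-image generation assumes sequential slices of one reconstruction;
  it is undefined across series boundaries.
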