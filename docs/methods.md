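# Methods

## Problem and pipeline

`nodulect` classifies small solid pulmonary nodules in CT as benign or
malignant.  The pipeline has three stages:

1. **Preprocessing.** The annotated bounding box (six inclusive voxel
   coordinates) is cropped and padded into a cube whose side is the
   largest box extent, so resampling never distorts the nodule's aspect
   ratio.  Padding uses air (−1024 HU), which the retention mask always
   discards.  The HU cube is windowed and quantized to 256 gray levels,
   and a two-threshold Otsu search partitions the histogram into three
   bands by maximising the between-class variance
   σ²(K1, K2) = Σₖ Pₖ (mₖ − m_G)², k ∈ {1, 2, 3}.  The upper two bands
   are retained: the lowest band captures aerated parenchyma, the upper
   bands the solid nodule, its rim, and dense distractors.
2. **Radiomics.** A 107-dimensional feature vector is extracted from
   the native-resolution gray cube under the Otsu mask (never from
   augmented cubes).
3. **Fusion classification.** The masked cube, resampled to the network
   input side, feeds a 3D residual CNN; the feature vector feeds an
   MLP; their 256-d embeddings are concatenated (512-d) and classified
   through dropout and a single-logit sigmoid.

## Otsu conventions

* The level at a threshold belongs to the lower band (the band masses
  are P₁ = Σ_{i≤K1} pᵢ, P₂ = Σ_{K1<i≤K2} pᵢ, P₃ = Σ_{i>K2} pᵢ), so the
  mask keeps voxels strictly above round(K1).
* The search is exhaustive over 1 ≤ K1 ≤ 253, K1 < K2 ≤ 254.  When the
  maximum is attained by several pairs (common when the histogram has
  empty gaps, since any threshold inside a gap yields the same
  partition of occupied levels), each returned threshold is the
  arithmetic mean of its tied candidates and may be fractional.
* Tie detection uses a relative tolerance of 1e−9: mathematically
  identical σ² values computed through different summation orders can
  differ in the last float bits, and the tolerance must absorb that
  without merging genuinely distinct optima.  A consequence worth
  noting: for a histogram symmetric under i ↦ 255−i the tie-averaged
  pair satisfies K1 + K2 = 254 (the reflection maps (K1, K2) to
  (254−K2, 254−K1) because of the lower-band membership convention).
* The histogram driving the search is computed over the original
  bounding-box content only: padding (air, −1024 HU, gray 0) would
  otherwise claim the lowest band by itself and promote parenchyma into
  a retained band.  The resulting thresholds are applied to the whole
  cube, and padding always falls below K1, so it is never retained.
* The HU window before quantization defaults to (−1000, 400), covering
  aerated lung through soft tissue.  The fixed manual comparator
  windows at (0, 300) and keeps exactly the voxels inside that window;
  it is retained as the ablation alternative.

## Radiomic feature catalogue

Eight classes, 120 features total: first-order (19), 3D shape (16), 2D
shape (10), GLCM (24), GLRLM (16), GLSZM (16), NGTDM (5), GLDM (14).
The default profile feeding the classifier has 107 features: it drops
first-order standard deviation (the square root of variance), the two
shape compactnesses (monotone transforms of sphericity) and the whole
2D-shape class.  The NGTDM class has exactly the five canonical
features (coarseness, contrast, busyness, complexity, strength).
The 3D-shape class omits spherical disproportion (the reciprocal of
sphericity) to keep the class at 16 without redundant entries.

Conventions that matter for reproducibility:

* **Quantization.** All texture matrices (and first-order entropy /
  uniformity) use fixed-bin-count quantization: 32 equal-width levels
  over the masked intensity range.  Fixed bin count keeps matrix sizes
  bounded and the features deterministic under intensity rescaling.
* **Directions.** GLCM and GLRLM use the 13 unique 3D offsets at
  distance 1; matrices are counted inside the mask only, the GLCM is
  symmetrized (C + Cᵀ — forward and reverse pairs, so diagonal entries
  count twice), normalized per direction, and the *matrices* are
  averaged over directions before features are computed.  Zones
  (GLSZM) and neighbourhoods (NGTDM, GLDM) use 26-connectivity.
* **Degenerate inputs.** Correlation-type features are 1 when the
  gray-level variance vanishes; entropies use 0·log 0 = 0; NGTDM
  coarseness is capped at 1e6 when the weighted difference sum is 0;
  GLDM dependence counts (0..26 equal neighbours at α = 0) enter the
  emphasis formulas shifted by one so a dependence of zero stays
  finite.  Every feature is finite by construction — the MLP branch
  requires it.
* **Shape surfaces.** 3D surfaces are marching-cubes triangulations and
  2D boundaries marching-squares contours, both computed after a
  half-voxel (σ = 0.5) Gaussian smoothing of the binary mask.  Marching
  on the raw binary grid overestimates area by roughly 9% through
  staircase faceting, which is enough to invert isoperimetric orderings
  (a digital ball would score less spherical than it is); the smoothing
  brings digital spheres close to their analytic surface.  Masks too
  small to survive smoothing (e.g. a single voxel) fall back to the raw
  grid.  The 2D-shape input is the axial slice with the largest masked
  area.  Maximum 2D diameters are measured per plane orientation:
  "slice" ⟂ z, "column" ⟂ y, "row" ⟂ x.  Axis lengths are 4·√λ from
  the principal components of the voxel-center point cloud.

## Augmentation

Cubes (never feature vectors) are augmented with per-class
probabilities: random axis flip and random affine each with probability
0.7 for benign and 0.4 for malignant, and random rotation with those
same per-class probabilities about a random grid axis by an angle
uniform in (0, 35°] for benign and (0, 30°] for malignant.  Reading the
rotation probability as equal to the flip/affine probabilities is a
documented choice, configurable in `AugmentPolicy`.  Affine ranges
(scale 0.9–1.1, shear ≤ 5°, translation ≤ 2 voxels) are mild defaults
chosen to keep the nodule inside the cube.  Interpolation is trilinear
with zero fill and the output is clipped to the input intensity range.
The benign class, being the minority in clinical cohorts, can
additionally be oversampled with augmented copies
(`oversample_minority`).

## Network

The visual branch is a 3D ResNet-50-style backbone: a 7×7×7 stride-2
stem (64 channels), 3×3×3 stride-2 max pool, four bottleneck stages
repeated 3/4/6/3 with channel pairs (64, 256), (128, 512), (256, 1024),
(512, 2048), global average pooling and a linear projection to 256.
Batch normalization and ReLU follow every convolution; residual blocks
compute U(x) = R(x) + M(x) with an identity shortcut when shapes match
and a strided 1×1×1 projection otherwise.  The nominal feature-map
geometry (128 → 56 → 28 → 14 → 7) corresponds to a 256³ input, which is
not practical on a single CPU; because the backbone is fully
convolutional with global pooling, any input side works with the same
stride pattern and an identical parameter count, and `input_side` is a
configuration knob (64 by default, 32 in the scaled study).
`width_multiplier` scales all channel counts for desk-scale runs.

The radiomics branch is an MLP 107 → 256 → 256 with ReLU.  The head
concatenates both embeddings (512-d), applies dropout 0.5 and a single
linear logit; the sigmoid score is the malignancy probability.

The network is implemented in a small numpy core (`nodulect.nn`) with
explicit backpropagation: im2col + GEMM convolutions, batch-norm,
max/global-average pooling, inverted dropout and Adam.  Gradients are
verified against central finite differences in the test suite, and the
convolution against a direct-loop computation.  Float32 is the working
precision; float64 is available for gradient checks.

## Training protocol

Adam with β₁ = 0.9, β₂ = 0.999, initial learning rate 1e−3 decayed
×0.9 every 10 epochs, 100 epochs, batch size 16, dropout 0.5, binary
cross-entropy on the single logit.  "Every 10 iterations" is read as
every 10 epochs, and "dropping by 10%" as multiplicative ×0.9.
Augmentation is redrawn per epoch.  A stratified holdout (20% by
default) is carved from the training data and the retained weights are
those of the epoch with the best holdout accuracy.  Radiomic features
are standardised with training-set statistics; cubes are scaled to
[0, 1].  All randomness fans out from one seed.

Evaluation: accuracy, TPR and FPR from the confusion table at a 0.5
threshold; ROC by a sweep over distinct scores with trapezoidal AUC
(equal to the Mann–Whitney rank statistic, which the tests assert to
1e−12).  Micro/macro AUC for the binary task are defined one-vs-rest:
macro is the mean of the two per-class AUCs (equal to the positive-class
AUC by symmetry of the complement scores); micro pools the 2n
(sample, class) indicator pairs with per-class scores (1−s, s).  The
five-fold protocol shuffles and deals round-robin; the pipeline uses a
stratified variant (the same split applied per class) so small
validation folds always contain both classes.

## Synthetic phantoms

The phantom generator stands in for the non-public clinical cohorts and
defines the study conditions of every end-to-end result.  Each phantom
is a 48³ volume (1 mm isotropic): parenchyma background at −900..−700
HU with smooth spatial variation, one solid nodule rendered as a
lobulated sphere with optional Gaussian-bump spicules and textured HU,
1–2 vessel-like cylinders of radius ≈1.1 voxels threaded past the
nodule surface (so they cross the bounding box), occasional −1000 HU
air pockets, a scanner point-spread blur (Gaussian, σ = 0.7 voxels) and
additive Gaussian noise (σ = 15 HU).  The blur is load-bearing: it
creates the partial-volume rim that real CT shows at tissue
boundaries, giving the histogram a genuine third population so the
two-threshold Otsu split lands between parenchyma and solid tissue
rather than inside the background cluster.

Class conditioning is geometric and textural, never positional:
benign nodules draw radius 4–6 voxels, mean 25–60 HU, texture σ 8–15
HU, 0–1 spicules and mild lobulation; malignant draw radius 6–9, mean
60–115 HU, texture σ 20–35 HU, 4–8 spicules and stronger lobulation.
The ranges abut but barely overlap, making the task learnable by both
branches without being trivial at nodule level.

What the phantoms do **not** model: airway trees, fissures, pleural
attachment, realistic vessel trees, scanner-specific noise spectra, or
inter-annotator bounding-box variability.  Passing the end-to-end tests
therefore demonstrates that the pipeline is wired correctly and can
exploit class-separable geometry and texture — not that it reaches any
particular accuracy on clinical data.

## Scaled study conditions

End-to-end checks run at desk scale: 200 phantoms (balanced), network
input side 32, width multiplier 0.25, 30 epochs, 160/40 train/test
split.  These sizes are the package's documented study conditions for
the synthetic cohort; the library defaults (input 64, width 1.0, 100
epochs) remain available for larger runs.

## Known limitations

* The brute-force Otsu agreement and all end-to-end numbers are
  established on synthetic data only; clinical generalisation is
  untested by construction.
* Texture features follow the direction-averaged-matrix convention;
  packages that average per-direction feature values will differ
  slightly on anisotropic textures.
* DICOM reading assumes a single axial series with consistent rescale
  tags; no de-identification or multi-frame support.
* The numpy network trains on one CPU; there is no GPU path.
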