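# Methods

## Problem and pipeline

`thyrocad` classifies thyroid nodules in B-mode ultrasound stills as benign
or malignant from second-order texture alone. The pipeline is deliberately
classical:

1. **Geometry** — every image is resized to 256 × 256 px (bilinear).
2. **Denoising** — a k × k median filter (default k = 3) with zero padding
   removes salt-and-pepper impulse noise. Zero padding darkens a one-pixel
   border (the corners most visibly, since five of their nine neighborhood
   positions are padding); this artifact is part of the pipeline's
   definition and is harmless because the nodule ROI never includes it in
   practice.
3. **Segmentation** — a single global threshold (Otsu by default, a fixed
   intensity optionally) splits the image into bright (1) and dark (0)
   pixels; the nodule, being hypoechoic, is the largest 4-connected dark
   component that does not touch the image border, subject to a minimum
   area (default 25 px). Border-touching components are excluded first so
   that the dark rim/background of a fan-beam image cannot win; if no
   interior component qualifies the largest sufficient dark component is
   used regardless of border contact, and if none exists the features fall
   back to the whole image with a logged warning.
4. **Texture** — the ROI bounding box (expanded by a 2-px margin) is
   min–max quantized to N = 8 gray levels and the gray-level co-occurrence
   matrix (GLCM) is built at distance 1 for the four standard angles
   (0°, 45°, 90°, 135°), symmetric, each normalized to a probability
   matrix p(i, j). Seven features are computed per angle and averaged:
   energy Σp², correlation Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ), entropy −Σp·log₂p,
   homogeneity Σp/(1+|i−j|), cluster shade Σ(i+j−μₓ−μᵧ)³p, contrast
   Σ(i−j)²p, and the inverse difference moment Σp/(1+(i−j)²).
5. **Classification** — a from-scratch feedforward network (7 → 10 → 1,
   sigmoid activations, full-batch gradient descent on cross-entropy,
   learning rate 0.1, ≤ 2000 epochs, loss-delta tolerance 1e-6) and a
   kernel SVM (RBF, C = 1, gamma scaled by feature count and variance; the
   quadratic program is solved by scikit-learn's SVC and the decision
   function Σαᵢyᵢk(xᵢ,x)+b is re-evaluated from the stored dual solution).
   Features are z-scored with training-split statistics only (population
   sd; constant features are flagged and zeroed).
6. **Evaluation** — confusion-matrix metrics with malignant as the positive
   class, ROC by a descending sweep over unique scores with trapezoidal
   AUROC, and an operating point minimizing the Euclidean distance
   √(FPR² + (1−TPR)²) to the ideal corner (0, 1), ties broken toward higher
   TPR. Metrics with zero denominators are reported as NaN with an explicit
   reason, never silently imputed.

The protocol default split is 87:13, stratified by label with per-stratum
rounding (33/66 cases → 29/57 train, 4/9 test), deterministic under a seed,
and groupable by case id so multiple images of one case never straddle the
split.

## Numerical conventions

- Entropy uses log base 2 with 0·log 0 = 0.
- Correlation with a zero-variance marginal (a delta GLCM) is defined as 1,
  the dominant convention in texture libraries.
- Homogeneity and the inverse difference moment differ only in the penalty
  on off-diagonal mass (1+|i−j| vs 1+(i−j)²); both are kept because they
  respond differently to mild vs strong gray-level jumps.
- Quantization is min–max over the crop's own range; a constant crop maps
  to level 0 and yields the degenerate delta GLCM (energy 1, entropy 0).
- Otsu's threshold t maximizes between-class variance of the {v < t} /
  {v ≥ t} split over t ∈ 1..255, ties toward the lowest t; binarization is
  v ≥ t → 1.
- The median filter's kernel is odd by construction so the median is always
  a single order statistic; no averaging rule is needed.

## The phantom generator

Clinical images cannot ship with the package, so every test and the
acceptance study run on synthetic ultrasound phantoms. Each case is built
as: a constant parenchyma background (mean 140); one dark elliptical
nodule (semi-axes 10–20% of the image side, random orientation); for
malignant cases an irregular margin (a random 2nd–6th-harmonic Fourier
perturbation of the boundary radius with total amplitude 0.35 of the
radius), marked hypoechogenicity (mean 45 vs 60 for benign), a
heterogeneous interior and five punctate bright microcalcifications
(≈3 px, intensity 235); then unit-mean multiplicative speckle (gamma
distributed, sd 0.25) and 2% salt-and-pepper impulses; finally clamping to
[0, 255]. The ground-truth mask is the noiseless interior of the realized
boundary. Labels map to synthesized TI-RADS categories (benign → 2/3,
malignant → 4a–5) so the metadata path is exercised end to end. At 99
cases the default benign fraction of 1/3 yields exactly 33 benign and 66
malignant.

The within-nodule heterogeneity is a Gaussian random field with a 1-px
correlation length and sd 4 (benign) vs 35 (malignant) gray levels. The
malignant sd is deliberately large relative to the speckle floor: because
speckle is multiplicative, a darker (more hypoechoic) nodule carries *less*
absolute speckle than the background, so without strong internal texture a
malignant nodule would paradoxically measure smoother than a benign one.
The chosen value makes the generator encode what it is meant to encode —
malignant interiors that are measurably rougher (higher GLCM contrast and
entropy, lower homogeneity) than benign ones — which is the property that
makes the downstream classifier experiments meaningful.

What the phantoms do **not** emulate: beam-dependent point-spread
anisotropy, attenuation and shadowing (including the acoustic shadows real
calcifications cast), cystic components, surrounding anatomy, probe
artifacts, or inter-scanner variation. Passing results on phantoms
therefore demonstrate the internal correctness and discriminative
machinery of the pipeline, not clinical performance; on real data the
class overlap is far larger and hold-out accuracy will be correspondingly
lower.

## Problem sizes

The packaged studies use sizes chosen to keep the full suite comfortably
interactive: 200 phantom images for the classifier study (87:13 split,
26 held-out cases; the split-seed comparison repeats training over 20
seeds), 50 + 50 phantoms for the texture-separability check, 50 for the
segmentation-overlap (Dice) check, and 10 for the impulse-repair rate.
Oracle-equivalence suites run on 100 random small rasters each.

## Known limitations

- A single global threshold assumes one dominant dark nodule on a brighter
  background; diffuse disease, multiple nodules (only the largest dark
  component is selected) and predominantly cystic/anechoic surroundings
  break the assumption.
- GLCM features are computed on the rectangular ROI crop, so a fringe of
  background pixels contributes to the statistics; this is intentional
  (the margin is part of the texture signature) but means the features are
  not a pure interior measurement.
- The ANN is a small fixed architecture with full-batch gradient descent;
  it is adequate for seven features but makes no attempt at modern
  regularization or scheduling.
- No cross-validation or hyperparameter search is performed; the protocol
  is a single stratified hold-out split by design.
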