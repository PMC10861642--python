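# Methods

## Pipeline overview

`tumortex` maps a 2-D grayscale image to a fixed-length composite texture
vector and classifies images with a linear SVM. The pipeline assumes
texture — the spatial arrangement of gray levels — is the discriminative
signal; it deliberately uses no shape, location, or intensity-calibration
information. All stages are deterministic functions of their inputs and
configuration.

## Image ingestion

Raster images (PNG/JPEG/TIFF) are collapsed from RGB to one channel with
ITU-R BT.601 luma weights (0.299, 0.587, 0.114) and quantized to integers in
`[0, L-1]` by round-half-up after rescaling from the source dtype range;
`L = 256` by default. Gray input is only quantized, so loading a saved 8-bit
grayscale PNG is idempotent. The Figshare brain-tumor reader accepts the
v7.3 (HDF5) `.mat` layout with a `cjdata` group (`image`, `label` with
1 = meningioma, 2 = glioma, 3 = pituitary) and min-max rescales each slice
to 8-bit. No denoising, resizing, or inter-patient intensity normalization
is performed: every downstream feature is size-normalized (normalized GLCM,
normalized LBP histogram), so the pipeline is resolution-agnostic.

## GLCM statistics

The co-occurrence matrix at distance `S` and angle θ counts ordered pixel
pairs at offset (row, col) = (0,+S) for 0°, (−S,+S) for 45°, (−S,0) for 90°,
(−S,−S) for 135°, with row 0 at the top. Defaults: `S = 1`, all four angles,
symmetric (transpose added) and normalized (sum 1). Symmetry and
normalization are required for the bounds `H, E ∈ (0, 1]` used in the range
invariants. `levels` defaults to 256 (no quantization loss); it can be
lowered (e.g. 8) to trade resolution for speed on very large images.

Two conventions deserve note:

- **Energy** is `sqrt(Σ P²)` by default (the square root of the angular
  second moment, matching the common library convention); a config flag
  `energy_mode="asm"` selects the raw second moment instead, since both
  readings of "energy" exist in the texture literature.
- **Correlation** at zero marginal variance (a constant image) is defined as
  1: a constant image is perfectly self-correlated, and this matches
  prevalent library behavior.
- **Homogeneity** is the inverse *difference* sum `Σ P/(1+|i−j|)`, not the
  inverse difference *moment* `Σ P/(1+(i−j)²)` used by scikit-image under
  the same name; the cross-check test against scikit-image therefore
  excludes homogeneity.

The per-angle 5-vectors `(C, D, H, E, Corr)` are averaged element-wise into
one orientation-pooled 5-vector. Pooling by averaging keeps the GLCM
contribution at exactly five features, which is the only layout consistent
with the composite-vector length below while still using all four angles.

## LBP

The classic 3×3 operator (equivalent to 8 sampling points at radius 1 with
nearest-neighbor sampling — no interpolation scheme is used): each of the 8
neighbors is compared to the center with `neighbor ≥ center → 1`, ties
counting as 1, and bits are packed clockwise from the top-left neighbor
(bit p has weight 2^p). Border pixels are excluded. Any fixed bit order
permutes histogram bins consistently, so histograms remain comparable within
a run; the chosen order is fixed and documented here. The histogram has
2⁸ = 256 bins and is normalized to sum 1, making it invariant to image size
and to adding a constant to all pixels. Rotation-invariant and "uniform"
LBP variants are out of scope.

## Composite vector

Block order: `glcm(5), lbp(256), interaction(1280), aggregated(3),
statistical(3)` → 1547 features. The interaction block is the outer product
`g ⊗ l` flattened row-major; because `l` sums to 1, the block sums to
`Σ g_i`, a useful algebraic check. Aggregated features use the sorted-
midpoint median. Statistical features use population (1/m) moments —
variance, skewness, excess kurtosis (the −3 convention) — with the
degenerate `std = 0` case mapped to skewness = kurtosis = 0 so constant
textures stay finite.

The log-transform block `log(1 + g)` is off by default: 1547 = 5 + 256 +
1280 + 3 + 3 only holds without it. `include_nonlinear=True` either appends
it (`nonlinear_mode="append"`, 1552 features) or substitutes it for the raw
GLCM block (`"substitute"`, 1547 features); both readings of "six blocks vs.
a 1547-length vector" are thereby available, and the interaction block
always uses the raw GLCM values. The natural logarithm is used; inputs must
exceed −1 (guaranteed for all five GLCM statistics, whose minima are −1 for
correlation only in pathological matrices and ≥ 0 otherwise).

## Classification and evaluation

Features are z-scored with train-set statistics (constant columns get unit
scale) before a one-vs-rest squared-hinge linear SVM (`C = 1.0` default,
fixed seed); raw blocks span several orders of magnitude (contrast ~10⁴ vs.
LBP frequencies ~10⁻²), so standardization is essential for conditioning.
Splits are stratified (default 80/20) and seeded.

Metrics come from the K×K confusion matrix under one-vs-rest reduction:
accuracy, precision, recall, F1, sensitivity, specificity, TPR, FPR, FNR,
TNR per class, macro-averaged headline values, and pooled (micro) accuracy
`trace/n`. FNR and TNR are computed structurally as `1 − TPR` and `1 − FPR`
so the complement identities hold even for a degenerate class with no
positives (where a 0/0 rate is defined as 0). Per-class Dice
`2TP/(2TP+FP+FN)` is reported although it is algebraically identical to
per-class F1 — it is a conventional headline number in tumor-image work,
where it is usually a segmentation-overlap measure; here it is the
confusion-matrix analogue. An empty-vs-empty class (2TP+FP+FN = 0) gets
Dice 1 with a warning. ROC curves sweep thresholds over the decision scores
(trapezoidal AUC, tied scores counting half, equivalent to the pairwise
win-rate); the micro-average pools all (score, binary label) pairs across
classes. The learning curve stratified-subsamples each CV fold's training
portion at a list of fractions and reports mean ± sd of train and
validation accuracy.

## Synthetic study conditions

The default synthetic dataset is 3 classes × 100 images of 64×64 pixels:

- `smooth` — Gaussian white noise low-pass filtered at correlation length
  8 px, then min-max rescaled to [0, 255] (low local contrast);
- `speckle` — i.i.d. uniform noise (maximal local contrast);
- `grating` — a horizontal-period-8 sinusoid with additive Gaussian noise at
  10 % of the intensity range (anisotropic).

These emulate what the three tumor classes are to the descriptor — classes
distinguishable by second-order texture statistics — without claiming
visual realism: no anatomy, no tumor masks, no intensity-inhomogeneity
fields, no inter-patient variation. Passing tests therefore demonstrate that
the pipeline separates texture-separable classes, not that it reaches any
particular accuracy on clinical MRI. Per-image seeds are SHA-256 hashes of
`seed|class|index` (reduced below 2³¹), so any single image can be
regenerated without building the whole set and datasets are bit-identical
across platforms.

Problem sizes were chosen so the full pipeline runs end-to-end in seconds:
300 images of 64×64 at 256 gray levels, 5-fold learning curves at fractions
0.25/0.5/1.0. On these conditions the held-out metric battery sits at the
1.0 ceiling — the synthetic classes are far easier than real MRI, which is
the intended role of a correctness (not difficulty) benchmark.

## Numerical choices and degenerate inputs

- GLCM normalization is validated to 1e−9 before statistics are computed;
  brute-force oracle agreement is asserted to 1e−10.
- Round-half-up (`floor(x + 0.5)`) everywhere quantization occurs, avoiding
  banker's-rounding surprises on exact halves.
- Feature CSVs format floats with 17 significant digits, so write/read
  round-trips are bit-exact (`pandas` reads with `float_precision=
  "round_trip"`).
- Constant images: GLCM correlation 1, LBP codes all 255, statistical
  skew/kurt 0 — every extractor returns finite values.
- Strict config parsing: unknown YAML keys raise instead of silently
  falling back to defaults.

## Known limitations

- Only the 8-point/radius-1 LBP geometry is implemented.
- GLCM distances > 1 are configurable but untested against references.
- The Figshare downloader is a convenience; no checksum verification.
- Duplicating every training sample shifts the regularized SVM optimum
  slightly (the hinge-loss term doubles relative to the regularizer);
  predictions on well-separated data are unaffected.
- DSC here is the confusion-matrix Dice, not a spatial-overlap measure; the
  two coincide only at the whole-slice classification level.
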