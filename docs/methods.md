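# Methods

This note documents the models, parameter choices and numerical decisions
behind `hemark`, and what the synthetic validation does and does not show.

## Stain model and separation

Stain separation assumes the Beer–Lambert mixing model: each pixel's
optical density vector is a non-negative combination of per-stain unit OD
vectors. We use the published Ruifrok–Johnston H&E vectors
(H = (0.650, 0.704, 0.286), E = (0.072, 0.990, 0.105), rows unit-normalized)
with the residual channel as their normalized cross product, overridable via
configuration for laboratories with calibrated vectors. OD is computed as
`−log10((I+1)/255)` — the +1 keeps saturated black finite and costs at most
one gray level of bias. Concentrations are the OD projected through the
inverted matrix, clipped at zero and divided by `log10(255) ≈ 2.407` (the
largest OD an 8-bit pixel can express) to land in [0, 1]. A matrix whose
unit-row condition number exceeds 1e8 is rejected as singular. No attempt
is made to estimate stain vectors from the image (Macenko-style); stain
variation across scanners/labs is a known limitation.

The synthetic generator renders through the exact forward model
(`pixel = round(255·10^(−OD)) − 1` plus a constant background density that
makes the empty slide ≈ 245 gray), so separation recovers the generating
concentrations to within 8-bit quantization — this closes the loop for the
round-trip tests. At high combined OD (dark pixels < ~15 gray) quantization
dominates: one gray step there is ~0.03–0.06 OD, which the tests account
for explicitly.

## Tissue masking

Tissue is "darker than background" in luminance. An H&E luminance histogram
is usually trimodal — white background, pink stroma, dark nuclei — and a
plain two-class Otsu split can lock onto the nuclei/rest boundary instead
of the background/tissue one when tumor is dense. We therefore take the
upper threshold of a three-class Otsu split, which always isolates the
bright background mode and coincides with the classic threshold on bimodal
input. Near-constant images have no split at all and are called
all-background if bright, all-tissue if dark, with a warning. Objects
smaller than 64 px are dropped. Limitation: a raster with no background at
all (tissue filling the frame) would misclassify its brightest tissue mode
as background.

## Tile features (schema `hemark-1`)

Tiles are 31×31 px, non-overlapping, floor-division grid, kept when ≥ 50%
tissue. The working descriptor has 45 features per channel × 3 channels
(haematoxylin, eosin, luminance) = 135. The individual statistics within
the four classical families are this package's selection, frozen under the
schema version:

* **Histogram (7)** — over a 256-bin histogram of the [0, 1] channel:
  mean, sd, smoothness `1 − 1/(1+σ²)`, skewness, excess kurtosis,
  uniformity `Σp²`, entropy `−Σp·log2 p`. Skewness/kurtosis of a constant
  tile are defined as 0.
* **Co-occurrence (16)** — symmetric GLCMs at distance 1 quantized to 32
  levels, the four direction matrices (0°, 45°, 90°, 135°) normalized then
  averaged before statistics: contrast, dissimilarity, homogeneity, ASM,
  energy, correlation, entropy, variance, sum average, sum variance, sum
  entropy, difference variance, difference entropy, information measures of
  correlation 1 and 2, maximum probability. Entropies in this family use
  natural logs so IMC2's exponential form is self-consistent. A constant
  tile has correlation 1 and IMC terms 0 by convention.
* **Spectral (15)** — the tile mean is subtracted, the residual zero-padded
  to 32×32, and the centered power spectrum (DC removed) binned into 8
  equal-width radial rings covering every AC frequency and 7 angular wedges
  over [0, π) (the spectrum of a real image is point-symmetric). Each bin
  is a fraction of total AC power, so each family sums to 1; a constant
  tile is all zeros. Mean subtraction before padding matters: padding a
  constant tile directly would fabricate edge power.
* **Moments (7)** — Hu's invariants of the tile treated as a mass
  distribution, compressed as `sign(φ)·log10(|φ|+1e−30)`; the 7th enters by
  magnitude so mirror images map to identical features. All-zero tiles give
  zeros.

Each family is verified against an independent brute-force implementation
(naive pair enumeration for the GLCM, direct formulas for the histogram,
direct spectrum fractions, rotated/mirrored copies for the moments).

## Classifier

A Gaussian-RBF SVM on z-scored features (columns constant up to roundoff
are dropped and recorded). Hyperparameters come from a grid search —
C ∈ {0.1, 1, 10, 100}, γ ∈ 10^{−3..1} log-spaced — scored by stratified
5-fold cross-validated accuracy with a fixed shuffle seed, refit on all
data. Posteriors are Platt-style sigmoid calibration fitted on internal CV
folds (`CalibratedClassifierCV(..., ensemble=False)`). The decision
threshold is 0.5 by default and the label is defined by
`posterior ≥ threshold`. Class weighting is available but off by default
(training sets here are balanced by construction).

On the synthetic tile sets the cross-validated accuracy is ~0.99. That is
a separability statement about the fixture's two texture classes, not a
claim about real tissue, where class appearance varies by subtype,
staining batch and scanner.

## Map cleaning and boundary

The classified grid is a three-state map (background/non-tumor/tumor). The
binary tumor layer is cleaned by: opening with a 2×2 square footprint,
closing with a 5×5 square, hole filling, and removal of components smaller
than 4 cells — iterated to a fixed point (so the operation is idempotent
by construction; the one-pass composition is not). Design reasoning, all at
the scale of a ~14×14 cell grid for a 512 px working raster:

* square (8-connected) footprints, because a diamond element clips the
  corners of every rectangular region at this resolution;
* the opening footprint is deliberately small: a 3×3 opening erases a
  genuine focus three cells across whose classification is ragged, while
  2×2 still removes isolated false-positive cells and one-cell-wide debris
  *before* the closing could absorb them (closing first was tried and
  rejected — it merges nearby false positives into surviving blobs and
  biases the percent estimate upward);
* morphology runs on a False-padded copy of the grid so regions near the
  tissue edge erode correctly (grayscale-morphology border padding
  otherwise anchors dilations to the array edge);
* the minimum region size (4 cells) is matched to the smallest focus the
  opening can preserve (a 2×2 core); all four parameters are configurable.

Each surviving component's contour is traced at the half-cell level,
resampled to 1024 points by arc length, encoded as the complex sequence
x + iy, low-pass filtered by keeping harmonics |k| ≤ 32, and
inverse-transformed; keeping all harmonics is the identity, which the tests
assert. Contours nested inside another (hole traces) are dropped — hole
filling has already removed true holes. Polygons are oriented CCW and
exported as GeoJSON in pixel coordinates; a slide whose cleaned map has no
tumor cells gets an empty boundary, which is the non-tumor slide call.

## Percent tumor nuclei

Nuclear content is segmented by a local-mean adaptive threshold on the
haematoxylin channel (block 51 px, offset 0.02 on the [0, 1] scale, specks
under 8 px removed) — the rule is a difference against the local mean, so
it is invariant to adding a constant to the channel. The modal
single-nucleus area is the median of connected-component areas inside the
plausible range 20–400 px² (≈3–11 μm nuclear diameters at 0.5 μm/px);
this stays on the singleton mode while singletons are the majority, without
any per-nucleus instance segmentation. Counts inside/outside the boundary
are nuclear area divided by the shared modal area, which makes the counts
exactly additive and the percent equal to the nuclear-area fraction inside
the boundary (the modal area cancels). A tile-area-only percentage is also
reported for comparison; it systematically disagrees whenever the tumor and
non-tumor compartments differ in nuclear density, which is exactly why the
count-based figure exists.

## Concordance metrics

Computed at pixel level on aligned masks: inclusion `100·|A∩M|/|M|`
(NaN when the manual mask is empty), exclusion `100·|(T∖M)∖A|/|T∖M|`
(NaN when the manual annotation covers all tissue), concordance index as
Dice with a Jaccard switch (two empty masks agree vacuously: 1), area FDR
`|A∖M|/|A|` (NaN when A is empty) plus a nuclei-weighted variant, and a
slide-level ROC where each slide is the point
(1 − exclusion/100, inclusion/100), anchored at (0,0)/(1,1), AUC by
trapezoid. The weighted acceptance threshold is
`w_non/(w_mal + w_non)`; weighting malignant identification twice as
heavily as non-malignant gives 1/3. Percent-tumor comparison reports
Pearson r (NaN-flagged for zero variance), the maximum absolute deviation
and a per-case table.

## Synthetic slides: what they emulate, and what they don't

A slide is a white frame (~245 gray plus OD noise) around an eosin-stained
tissue block; tumor regions carry dense, near-round, larger nuclei
(default 8 per 1000 px², equivalent radius 3.5 ± 0.4 px, axis ratio 1.2)
and stroma carries sparser elongated nuclei (4 per 1000 px², 3.3 ± 0.4 px,
axis ratio 3). Nuclei are placed by rejection sampling against an occupancy
raster (cap 1000 attempts each), never overlap, and are fully contained in
their region, so the class of every nucleus is unambiguous and the true
percent tumor is an exact count ratio. Per-channel OD noise (sd 0.01) is
added before rendering. A fixed seed reproduces the slide byte for byte.

Default densities were set so that the two classes are separable by both
density and morphology while a low-percent focus still spans ≥ 3 tiles on a
512 px slide; nucleus sizes of the two classes are kept close (area ratio
≈ 1.12) because the single-modal-area estimator equates percent with
nuclear-area fraction, and a large systematic size difference between
classes would bias it (by about `k·p/(k·p+1−p)` for area ratio k — ≈ +3
points at p = 0.5 for the defaults, and this is a real limitation of
area-based counting on tissues whose tumor nuclei are much larger than
stromal nuclei).

Not emulated: chromatin texture inside nuclei, cytoplasm/gland
architecture, necrosis, inflammation, staining batch variation, scanner
color profiles, compression artifacts. Passing the recovery experiment
therefore demonstrates the internal consistency of the pipeline — tiling,
features, classification, boundary geometry and count arithmetic — not
clinical performance on real H&E, whose texture classes are far less
separable.

## The recovery experiment

Ten 512×512 slides (one centered tumor square each) span ~10–90% true
percent tumor. With class textures held fixed, the percent is spanned by
region size: the tumor area fraction solves
`f = p·d_s / (d_t·(1−p) + p·d_s)` for target percent p with densities
(d_t, d_s) = (8, 4). Density-only spanning is infeasible — non-overlapping
nuclei cap the achievable coverage — and a classifier can only generalize
across slides if class appearance is constant. The tile classifier is
trained on 150 tiles per class sampled from two separate fixture slides,
then the full annotate + percent pipeline runs on each test slide and the
maximum absolute deviation from the generator truth is reported
(`scripts/acceptance.py`; observed 2.5–5.9 points across several seeds).
Problem sizes (512 px slides, 300 training tiles) were chosen to keep the
whole experiment under a minute on one CPU while leaving every stage of the
pipeline non-trivially exercised.

## Degenerate inputs and conventions

Coordinates are 0-based (row, col) with half-open windows; boundaries are
reported in level-0 pixel coordinates as (x, y) = (col, row) GeoJSON rings.
Uniform images, empty masks, empty boundaries, single-class training sets,
zero-variance feature columns, images smaller than one tile, and
undefined rates all have explicit, tested behavior (error, warning, NaN
flag or empty result as documented per function). Undefined statistics are
NaN rather than silently 0 so that aggregation can skip them.
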