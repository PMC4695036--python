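# hemark

Automated tumor annotation and percent-tumor-nuclei estimation for
H&E-stained histology rasters.

## The problem

Molecular assays on solid-tumor FFPE sections (e.g. *EGFR*/*KRAS* mutation
panels in non-small-cell lung cancer) need enough tumor DNA in the
macrodissected sample. In practice a pathologist reviews the H&E slide,
eyeballs the percent tumor nuclei, and hand-draws the region to scrape —
both steps are subjective and known to vary by tens of points between
observers. `hemark` automates them: it classifies tissue tiles as tumor or
non-tumor from texture features, turns the classified map into a smooth
closed boundary suitable for macrodissection, and estimates the percent
tumor nuclei from nuclear content inside vs. outside that boundary. It also
implements the concordance statistics used to validate such a system
against manual annotations, and a synthetic slide generator with exact
nuclei-level ground truth so the entire pipeline is testable without any
real slide.

## Method

For a slide raster *I* (RGB, ~0.5 μm/px working resolution):

1. **Background removal** — Otsu-style thresholding of luminance (upper cut
   of a 3-class split, robust to the trimodal background/stroma/nuclei
   histogram of H&E).
2. **Stain separation** — color deconvolution: per-pixel optical density
   `OD = −log10((I+1)/255)` is projected through the inverse of the
   Ruifrok–Johnston H&E stain matrix, yielding haematoxylin, eosin and
   luminance channels.
3. **Tiling and features** — tissue is cut into non-overlapping 31×31
   tiles; each tile yields a 135-dimensional descriptor: per channel,
   7 histogram statistics, 16 gray-level co-occurrence (Haralick-style)
   statistics, 15 Fourier ring/wedge spectral energy fractions, and 7 Hu
   moment invariants (45 × 3 channels).
4. **Classification** — a Gaussian-RBF SVM, selected by grid-searched
   stratified 5-fold cross-validation over (C, γ) with z-scored features
   and Platt-style sigmoid posterior calibration, labels each tile and
   assigns a tumor posterior in [0, 1] (renderable as a blue→red TumorMap
   heatmap).
5. **Boundary** — the binary tumor tile layer is cleaned (opening, closing,
   hole filling, small-region removal, iterated to a fixed point); each
   component's contour is resampled to 1024 points, encoded as complex
   Fourier descriptors, truncated to the first 32 harmonic pairs and
   inverse-transformed — a smooth closed polygon in pixel coordinates.
6. **Percent tumor nuclei** — local-mean adaptive thresholding of the
   haematoxylin channel segments global nuclear content; a modal
   single-nucleus area is fitted from plausible connected components, and
   nuclei counts inside/outside the boundary follow as nuclear area divided
   by modal area, giving `% tumor = 100·N_in/(N_in+N_out)`.

Evaluation utilities compute inclusion rate `100·|A∩M|/|M|`, exclusion rate
`100·|(T∖M)∖A|/|T∖M|`, concordance index (Dice `2|A∩M|/(|A|+|M|)`), area
FDR `|A∖M|/|A|` with the weighted acceptance threshold
`FDR′ = w_non/(w_mal+w_non)` (0.33 at 2:1 weighting), a slide-level ROC/AUC,
and percent-tumor correlation against benchmark counts.

## Worked example

Everything below runs from scratch in a few seconds using the synthetic
fixture generator (no data download):

```bash
cat > synth.yaml <<'YAML'
width: 512
height: 512
tissue_margin_px: 32
tumor_nucleus_density: 8.0
stroma_nucleus_density: 4.0
YAML

hemark synth --config synth.yaml --out fixtures --seed 11 --tumor-side 224 --tiles 100
hemark train --features fixtures/train.csv --out model.bin --seed 11
hemark annotate --model model.bin --image fixtures/slide.png --out annotation
hemark percent-tumor --model model.bin --image fixtures/slide.png --out percent.json
```

which prints:

```
slide: fixtures/slide.png  true % tumor = 39.98
training features: fixtures/train.csv (200 tiles)
model: model.bin  CV accuracy 0.9950  best {'svc__estimator__C': 10.0, 'svc__estimator__gamma': 0.001}
boundary polygons: 1  area: 46608 px  tumor slide: True
percent tumor nuclei: 39.52 (tile-area figure 25.00)
```

Reading the numbers: the generated slide truly contains 39.98% tumor
nuclei (exact count ratio from the generator). The tile classifier reaches
99.5% cross-validated accuracy on the 200 labeled fixture tiles; the
annotation step finds one tumor region of ~46.6 kpx and calls the slide
tumor-positive; the nuclei-count estimate of 39.52% lands within half a
point of truth, while the naive tile-area figure (25.00% — the fraction of
tiles called tumor) illustrates why area alone is not a cellularity
estimate: the tumor region is denser in nuclei than the stroma.
`annotation/` additionally contains the boundary as GeoJSON and a raster
mask, the TumorMap posterior heatmap, and the gray/white/black label map.

The same pipeline is available as a library (`hemark.generate_slide`,
`hemark.train`, `hemark.classify_slide`, `hemark.percent_tumor_pipeline`,
`hemark.evaluate_slides`); see the module docstrings.

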