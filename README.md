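# chromaroi

Region-of-interest (ROI) selection in heterogeneous 2D images for
multivariate calibration, built for pseudo-color GC×GC chromatogram
rasters and the prediction of wine age from them.

## The problem

A comprehensive two-dimensional gas chromatogram is usually inspected as a
pseudo-color image: a `J × K` raster whose colors encode peak intensity over
the two retention-time axes. Color-frequency histograms of such an image
make a perfectly good predictor block for regression — *if* the property of
interest is actually encoded everywhere in the image. In a heterogeneous
image it is not: only a few regions contain the compounds whose abundance
tracks the response, and histograms of the whole image dilute that signal
with matrix peaks common to every sample.

`chromaroi` finds the informative regions automatically:

1. the image is partitioned into a `roi₁ × roi₂` grid of subimages and
   unfolded row-major into a candidate vector **r** of length `roi₁·roi₂`;
2. a genetic algorithm searches over binary chromosomes `g ∈ {0,1}^(roi₁·roi₂)`
   (gene = subimage in/out, 1 ≤ Σg ≤ Nim). For each chromosome the pixels of
   the selected subimages are pooled into per-channel 256-bin color
   histograms (RGB by default; HSV and grayscale available), giving one row
   `x ∈ ℝ^(256·C)` per sample;
3. chromosome fitness is the RMSECV of a PLS1 regression (NIPALS,
   mean-centred) of the response **y** on those histograms under
   leave-one-out cross-validation — lower is better. Selection is
   roulette-wheel on 1/RMSECV, with single-point crossover, per-gene
   mutation, elitism, and a best-of-`n` restart loop (optionally a
   Monte-Carlo reliability loop reporting per-subimage selection
   frequencies);
4. the winning histogram can be refined further by interval selection:
   **iPLS** (one PLS-LOOCV model per contiguous bin window, ranked against
   the full-histogram baseline) and **iSPA-PLS** (successive projections
   over interval representatives, every candidate combination scored by
   PLS-LOOCV);
5. samples are split into calibration and prediction sets by **SPXY**
   (Kennard–Stone on max-normalised joint X–y Euclidean distances), and
   each model is reported with LV, RMSECV, REP, R², RMSEP and a one-sample
   Student-t bias test (`t_cal = |ē|√n / s_e` against the one-sided
   `t_crit` at 95%, df = n−1).

Because the wine chromatogram images themselves are not publicly
deposited, the package ships a first-class synthetic generator that
emulates their statistical structure — a noisy baseline, shared background
peaks, and planted Gaussian peaks whose amplitude grows with the response,
rendered through a colormap to 24-bit RGB — plus the transcribed 38-sample
wine table (28 calibration / 10 prediction, vintages 1989–2017) via
`chromaroi.table1_fixture()`.

## Worked example

Generate a synthetic set at the study conditions (38 samples, 5×5 grid,
two informative cells; image size reduced here for speed) and run the GA:

```bash
chromaroi simulate --out data --seed 1 --height 141 --width 239
chromaroi select-roi --config run.yaml
```

with `run.yaml`:

```yaml
sample_table: data/samples.csv
image_dir: data
output_dir: out
grids: [[5, 5]]
n_cal: 28
seed: 1
ga: {population_size: 24, generations: 15, nim: 4, n_restarts: 10, lv_max: 5}
```

prints (abridged):

```
     model grid  n_lv   rmsecv   rep_cv    r2_cv    rmsep  ...  t_cal   t_crit
full_image full     4 1.488630 0.073691 0.970294 1.082797  ... 2.837098 1.833113
  GA (5x5)  5x5     4 0.455519 0.022549 0.997218 0.633928  ... 2.668898 1.833113
```

Reading it: the full-image model predicts wine age with a cross-validated
error of 1.49 years; restricting the histogram to the four GA-selected
subimages cuts that to 0.46 years and the independent-set error from 1.08
to 0.63 years. `out/selected_roi_5x5.csv` lists the selected cells by
1-based (row, col) — here they include (2,3) and (2,4), exactly the two
planted cells. The subsequent interval stage

```bash
chromaroi intervals --config run.yaml
```

reports the best single 16-bin window and the iSPA-PLS interval
combination with their RMSECVs against the GA model's baseline.

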