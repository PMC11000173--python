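# Methods

## Model and procedure

The package treats a pseudo-color 2D chromatogram as a 24-bit RGB raster
`J × K` (J rows = second retention dimension, K columns = first). The
analytical signal is assumed to be *local*: a small number of rectangular
regions carry peaks whose intensity varies with the response (wine age, in
years), embedded in a background of matrix peaks shared by all samples.

ROI selection is a combinatorial search over subimage subsets. The image
is partitioned into `roi₂` rows × `roi₁` columns with boundaries
`floor(i·dim/roi)`, so blocks differ by at most one pixel per axis and no
pixel is dropped. Cells are labelled 1-based `(row, col)`, row 1 at the
top, and unfolded row-major (`index = (row−1)·roi₁ + col`); this order is
declared once and used in every report. The search space is binary
vectors over the unfolded cells with between 1 and `Nim` ones.

Features are pooled histograms: the pixels of all selected cells are
pooled and counted into one 256-bin frequency histogram per color channel,
concatenated in declared channel order (default R, G, B; H, S, V and
grayscale optional). Pooling — rather than concatenating per-cell
histograms — keeps the feature length at `256·C` for every chromosome, so
one PLS architecture serves the entire search; per-cell concatenation is
available behind a flag for comparison. Raw counts are kept (images share
dimensions, and PLS mean-centring absorbs the common scale); relative
frequencies are a config switch.

The regression is PLS1 by NIPALS on column-mean-centred X and mean-centred
y (autoscaling optional, off by default — centring is the minimal standard
treatment for count features on a common scale). Fitness of a chromosome
is the RMSECV of the leave-one-out refit loop. The latent-variable count
is chosen by a parsimonious rule: the smallest count whose RMSECV lies
within a relative tolerance (default 0) of the curve minimum, ties toward
fewer components. Because NIPALS components are nested, one LOOCV pass at
`lv_max` yields the held-out predictions for every smaller count, which is
what makes GA-scale fitness evaluation affordable.

GA operators: roulette-wheel parent selection with weights `1/RMSECV`
(the standard transform for a minimised fitness; chromosomes with
non-finite fitness are excluded from the wheel), single-point crossover at
a uniform cut, independent per-gene bit-flip mutation (a per-chromosome
variant is config-switchable), elitism carrying the top `⌈e·p⌉`
chromosomes unchanged, and a repair step restoring `1 ≤ ones ≤ Nim` after
the variation operators (set one random gene if empty; clear random ones
down to `Nim` if over). Constraint handling by repair rather than penalty
keeps every evaluation a meaningful model. Fitness is cached on the gene
pattern — it is a pure function of the genes for fixed data — and the
cache is shared across restarts of one run, which changes nothing
statistically and saves most of the runtime.

Sample splitting uses SPXY: Kennard–Stone selection on
`d(i,j) = dx(i,j)/max dx + dy(i,j)/max dy`, seeded with the
maximum-distance pair; ties break toward the lowest sample index for
determinism. When a sample table carries C/P labels (as the packaged
38-wine table does), those labels are honoured instead.

Figures of merit: RMSECV/RMSEP in response units, `REP = RMSE/ȳ` reported
as a dimensionless ratio, `R² = 1 − Σe²/Σ(y−ȳ)²`, and a one-sample
Student-t test of the prediction residuals against zero mean
(`t_cal = |ē|√n/s_e`, one-sided `t_crit` at the configured confidence with
n−1 degrees of freedom; 1.8331 at 95% for n = 10).

Interval selection operates on the winning histogram's feature axis, cut
into equal-width windows by the same floor-boundary rule (default 16
windows per 256-bin channel, i.e. 16-bin windows). iPLS fits one
PLS-LOOCV model per window and ranks them against the full-histogram
baseline; degenerate windows are recorded as unusable rather than fatal.
iSPA-PLS represents each window by its column-mean profile over samples
(mean-centred so projections compare shape, not offset), builds successive
projection chains from every start, and scores every chain prefix by
PLS-LOOCV; the global minimum wins, ties toward fewer windows. The
column-mean representative is a documented choice — the literature varies —
and is the hook to replace if another representative is preferred.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `grids` | (5,5), (10,10) | grid sweep; 15×15 supported |
| `channels` | R, G, B | histogram color models |
| `population_size` / `generations` | 100 / 100 | GA run size |
| `mutation_rate` | 0.05 | per-gene flip probability |
| `crossover_rate` | 0.65 | probability the parent pair recombines |
| `elitism_rate` | 0.10 | fraction carried unchanged |
| `Nim` | grid size | cap on selected subimages per chromosome |
| `n_restarts` | 10 | best-of-n independent GA runs |
| `lv_max` / `lv_tol` | 5 / 0 | LV search bound and parsimony tolerance |
| `n_cal` | 28 | SPXY calibration-set size |
| `confidence` | 0.95 | bias-test level |

The GA defaults are the reported operating point of the method
(population 100, 100 generations, 5% mutation, 65% crossover, 10%
elitism, best of 10). Published descriptions of the operator rates are not
fully consistent (1%/60% appears alongside 5%/65%); the defaults follow
the rates quoted for the actual experiment and all four are configurable.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` defaults describe a study-sized problem: 38 samples,
705 × 1195 px images, a 5 × 5 grid, responses uniform on 6–34 years
(the 1989–2017 vintage span against a 2023 reference; the reference year
is configuration, not data), and two informative cells at (2,3) and (2,4)
— the grid positions where age-discriminating compounds were reported.
Each sample's scalar field is `baseline (0.05) + pixel noise
(σ = 0.02) + 30 shared background Gaussian peaks (amplitude U(0.2, 0.7),
5% per-sample jitter) + 3 planted peaks per informative cell with
amplitude `0.025·y + noise``, clipped to [0,1] and mapped through a
jet-like colormap to RGB. Gain and noise were fixed once at values that
give the planted cells a clear but not overwhelming advantage over the
full image (per-cell signal-to-background comparable to a distinct minor
peak in a busy chromatogram).

Faithful aspects: pseudo-color rendering (histogram features arise from an
intensity→color mapping, not direct RGB noise), shared matrix background
(the full-image model works but is beatable), localized response-coded
signal. Not emulated: GC×GC peak physics (modulation phase, tailing),
retention-time misalignment between samples, detector saturation. Passing
tests therefore demonstrate that the search machinery recovers localized
signal under the method's own assumptions — not that any particular real
chromatogram set is predictable.

## Problem sizes used in the test suite

The suite and the acceptance script exercise the full pipeline at reduced
size so a complete run stays in the minutes range on one core: synthetic
images at 141 × 239 px (a fifth of the native geometry per axis, peak σ
scaled to 3 px), GA at population 24, 15 generations, `Nim = 4`, 10
restarts; the 4 × 4 exhaustive-comparison uses 18 samples at 64 × 96 px.
Sample count (38), grid (5 × 5), planted cells, noise and gain are kept at
the study conditions. The GA run size is the package's own desk-scale
operating point; the full 100 × 100 defaults remain the CLI defaults.

## Numerical choices and degenerate inputs

- NIPALS truncates when X or y deflates below 1e-12; a model with zero
  usable components raises a degenerate-input error, which the GA maps to
  an infinite fitness sentinel (logged, excluded from the roulette wheel).
- Constant feature columns are invisible to a centred PLS model; the
  fitness evaluator drops them purely to cut cost.
- Zero-variance responses, identical samples in X or y (SPXY), zero-spread
  residuals (bias test) and empty subimage selections raise typed errors.
- `pick_lv` tie-breaks toward fewer components; SPXY and iSPA-PLS
  tie-break toward the lowest index / fewest, lexicographically smallest
  interval set. All stochastic components draw from a single master seed
  via spawned `numpy` generators, so every report is byte-reproducible.

## Known limitations

- The LOOCV refit loop is O(I) PLS fits per fitness call; for populations
  ≫ 100 on dense grids the cache hit rate, not the fit cost, dominates
  wall time.
- Images are assumed mutually comparable (no registration/alignment
  stage); real chromatogram sets may need alignment upstream.
- The bias test assumes approximately normal residuals; with n = 10
  prediction samples it has limited power.
- iPLS reports a single best window by default; forward combination of
  top windows is deliberately left to iSPA-PLS.
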