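# Methods

## Model and pipeline

`hbm3d` classifies binary-labeled cohorts of volumetric images that share a
grid and a voxel→MNI affine (the expected input is T1-weighted MRI already
segmented and spatially normalized upstream; no registration is performed
here). The pipeline is a two-level ensemble:

1. **Local descriptors.** The volume is covered by an overlapping grid of
   cubic cells (side `cell_size` voxels; stride
   `max(1, round(cell_size·(1−overlap)))`; cells are half-open
   `[origin, origin+size)` and every cell lies fully inside the volume;
   origins are enumerated in raster order, x fastest). Per voxel, the
   gradient is computed by central differences with replicated borders and
   expressed as a magnitude plus two angles: azimuth θ from +x toward +y and
   polar angle φ from +z, in degrees. Each voxel votes its magnitude into an
   orientation bin (hard assignment); per-cell histograms are L2-normalized
   unless the norm is below 1e-12 (all-zero cells stay zero).
2. **Statuses and classifiers.** Each cell's descriptors across training
   subjects are clustered into k = 2 groups — the framework's compact
   representation is binary, so two clusters per cell is the natural (and
   only meaningful) choice. Which cluster is "0" is arbitrary and never
   canonicalized: downstream classifiers absorb the labeling, and the
   contribution analysis evaluates both states. A per-cell regional
   classifier (nearest centroid for k-means clusters; linear SVM for Ward
   clusters, whose centroids need not be representative) reproduces statuses
   at test time. The concatenated statuses feed a final SVM (linear kernel
   default) that makes the subject-level decision; its signed score is
   positive for the disease class, and a zero score resolves to the control
   class.

### Orientation partitions

Both schemes are parameterized by an even `n_dir2 ≥ 2`:

- *full*: `n_dir2` equal azimuth sectors × `n_dir2/2` equal polar bands →
  `n_dir2²/2` bins. Near the poles a tiny direction change can hop azimuth
  sectors, making the descriptor noise-sensitive there.
- *pole-merged*: polar caps of half-width `180/n_dir2` degrees become single
  bins (indices 0 and `n_dir3−1`); the remaining `n_dir2/2 − 1` equal polar
  bands × `n_dir2` sectors fill the middle → `n_dir2·(n_dir2/2−1) + 2` bins.
  This is the unique simple construction producing both reference counts
  (32 and 26 at `n_dir2 = 8`).

All intervals are half-open on the upper side except the closing boundary
(φ = 180° falls in the last band / south cap). Zero-gradient voxels carry
the conventional direction (0°, 90°) and a zero-weight vote, so no special
case reaches the histograms.

### 2D baseline

`extract_features_2d` slices the volume along one axis, computes in-plane
central-difference gradients, bins directions into `n_dir2` equal sectors
over 360°, and tiles each slice with squares under the same stride rule.
Every (slice, square) pair is one cell; the downstream pipeline is unchanged.
It exists as a contract-compatible comparator, not a recommended descriptor.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `n_dir2` | 8 | directions | the field-standard 2D direction count |
| `scheme` | pole_merged | — | 26 bins at the default `n_dir2` |
| `cell_size` | 14 | voxels | scan range of interest is 10–20 |
| `overlap_fraction` | 0.5 | — | scan range of interest is 0.2–0.5 |
| `normalize` | on | — | per-cell L2, ε = 1e-12 |
| SVM C | 1.0 | — | same C for regional and final SVMs, configurable |
| k-means | 10 restarts, k-means++ | — | 300-iteration cap, tol 1e-6, seeded |
| NB α | 1.0 | — | Laplace smoothing; keeps all logs finite |
| contribution threshold | 95th percentile | — | of the subject's own c(i, xᵢ); scale-free |
| CV | k = 10, 10 runs | — | master seed 20200508, configurable |

A single SVM regularization constant serves both levels because nothing in
the two-level design distinguishes their regularization needs and one knob
is easier to audit. The percentile threshold was chosen because contribution
magnitudes shift with cohort size, smoothing and grid geometry; a fixed
absolute cutoff would not transfer across configurations.

## Cross-validation and metrics

Folds are stratified by dealing each class round-robin after a seeded
within-class shuffle, so per-class fold counts differ by at most one. Each
run reshuffles with a run seed derived from the master seed via a seed
sequence. Per run, held-out predictions are pooled and the metric panel
computed on the pooled confusion counts; pooled panels are averaged across
runs (`summary`). Pooling is what makes integer correct/total counts
meaningful for a whole run. Because it is ambiguous whether F1/AUC style
summaries should be pooled or fold-averaged, the report also carries a
`fold_averaged` panel. Ratios with zero denominators are NaN, never zero by
fiat. AUC is the rank statistic (probability a random positive outranks a
random negative, ties ½), computed from final-SVM decision scores. Feature
extraction is cached across folds — descriptors are label-independent —
while clustering, regional and final classifiers are refit per fold.

## Naive Bayes contributions and annotation

Priors are raw class frequencies; conditionals use add-α smoothing. The
model serves explanation only — the SVM decides. Contributions are reported
per test subject, conditioned on that subject's statuses. Selected cells are
mapped center-first: cell center = origin + (size−1)/2 per axis (voxel),
through the volume affine to MNI mm, then through the inverse atlas affine
to the nearest atlas voxel; background or out-of-grid landings take the
nearest labeled voxel by Euclidean mm distance, ties to the smallest code.

## Phantom generator

Each phantom is a smoothed ellipsoid (interior intensity 100, Gaussian blur
σ = 2 voxels) plus i.i.d. Gaussian voxel noise (SD 1). Disease-class
subjects additionally carry a 3D sinusoidal grating (wavelength 4 voxels,
oblique orientation) confined to declared grid cells, with amplitude
`effect_size × noise_sd`. The grating is multiplied by a separable Hann
window inside each anomaly cell so its amplitude reaches zero at the cell
boundary: gradient stencils evaluated in neighboring cells reach one voxel
inside, and without the taper the anomaly would be measurable from adjacent
cells, making the localization ground truth ill-defined. A grating is used
because HOG is an orientation detector — the injected signal lives exactly
in the measured feature space, which makes recovery tests sharp.

Defaults (48³ volume, 12-voxel cells, no overlap → 64 cells, 20 subjects
per class, effect size 8) keep a full pipeline run under a minute on one
CPU while remaining strongly separable; effect size 0 gives an exact null.
What the phantom does *not* emulate: anatomy, tissue contrast, partial
volume effects, scanner/site heterogeneity, registration error, or
correlated noise. Passing phantom tests therefore demonstrates that the
pipeline recovers oriented-texture group differences it was designed to
measure and is correctly wired end to end — not that comparable accuracy
will be achieved on clinical MRI.

## Numerical choices and degenerate inputs

- Gradients: `correlate1d` with kernel (−½, 0, ½) and replicated edges;
  border voxels thus get halved one-sided differences.
- Tie-breaks are deterministic and conservative: equidistant-from-centroids
  descriptors take status 0; a zero final-SVM score predicts the control
  class; contribution ties order by cell index; annotation distance ties
  take the smallest atlas code.
- A cell whose training descriptors have fewer than two distinct values gets
  a constant status-0 model and a degenerate flag; identical compact vectors
  across both classes degrade the final classifier to a majority-class
  constant (ties → control).
- Determinism: every stochastic component (phantom noise, fold shuffles,
  k-means restarts) is seeded from the caller's seed; per-cell k-means seeds
  derive from a seed sequence so cells are decorrelated but reproducible.
- SVM decision values are reproducible to the solver tolerance (1e-3);
  exact identities are only asserted of quantities computed in closed form
  (NB decomposition, histogram mass).

## Evaluation scales used by the shipped checks

The automated checks run the full pipeline at phantom scale: 40 subjects,
48³ voxels, 64 cells, 10-fold CV with 3 runs for recovery/null calibration,
and 16-subject cohorts for determinism and contract checks. These sizes were
chosen so the whole suite exercises every code path in minutes on a single
CPU; the pipeline itself has no dependence on these sizes.

## Known limitations

- The regional linear SVM and final SVM share one C; no per-level or nested
  hyperparameter search is provided.
- NB contributions assume conditional independence of cell statuses, which
  spatially adjacent (especially overlapping) cells violate; contributions
  are a ranking device, not calibrated evidence.
- The 2D baseline inherits the 3D cell-status machinery but no claim is made
  about its descriptive power.
- Atlas annotation assigns one region per cell center; large cells spanning
  several regions are summarized by their center only.
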