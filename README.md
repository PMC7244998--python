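# hbm3d

Two-level **histogram-based morphometry (HBM)** for classifying spatially
normalized structural MRI volumes — developed around the problem of
distinguishing individuals with autism spectrum disorder (ASD) from healthy
controls (HC) using T1-weighted scans in MNI space, but applicable to any
binary group contrast on shared-grid volumetric images.

## The method

Whole-brain voxel vectors are too high-dimensional for the small cohorts
typical of neuroimaging studies. `hbm3d` instead builds a compact, binary,
interpretable representation in two levels:

1. **3D HOG descriptors per cell.** Each volume is divided into an
   overlapping grid of cubic cells. Voxel gradients (central differences)
   are expressed as an azimuth θ ∈ [0°, 360°) and polar angle φ ∈ [0°, 180°],
   and binned over the sphere under one of two partition schemes
   parameterized by an even 2D direction count `N_DIR2`:
   *full* (equal azimuth × polar patches, `N_DIR2²/2` bins — 32 at
   `N_DIR2 = 8`) or *pole-merged* (patches touching each pole collapse to a
   single cap bin, `N_DIR2·(N_DIR2/2 − 1) + 2` bins — 26 at `N_DIR2 = 8`),
   which removes the bin-assignment instability near the poles. Votes are
   magnitude-weighted; descriptors are L2-normalized per cell.
2. **Statuses and the final SVM.** Per cell, the training subjects'
   descriptors are clustered into two groups (k-means, or Ward hierarchical),
   giving each cell a binary status. A per-cell *regional classifier*
   (nearest centroid, or linear SVM) reproduces statuses for unseen
   subjects. Statuses concatenated in raster cell order form the compact
   representation X₀…Xₙ on which a final SVM (linear kernel by default) makes
   the subject-level call.

The four named instances are **KNS32**, **KNS26** (k-means + nearest
centroid + SVM on 32/26 bins) and **HSS32**, **HSS26** (hierarchical +
linear-SVM regional + SVM).

For interpretation, a Naive Bayes model over the same statuses gives each
cell a *feature contribution* c(i, s) = log P(Xᵢ=s|ASD) − log P(Xᵢ=s|HC),
with the exact decomposition

log [P(ASD|x) / P(HC|x)] = log [P(ASD)/P(HC)] + Σᵢ c(i, xᵢ).

High-contribution cells are mapped through the NIfTI affine to MNI
millimetre coordinates and annotated with region names from a user-supplied
parcellation (e.g. AAL); centers landing on atlas background take the
nearest labeled voxel.

Evaluation uses stratified k-fold cross-validation repeated over several
random shuffles, pooling held-out predictions per run, with the full metric
panel (ACC/SEN/SPE/PPV/NPV/F1 and rank-based AUC) and a cell-size × overlap
parameter scan.

A **phantom generator** produces labeled cohorts — a smoothed noisy
ellipsoid, with the disease class carrying a Hann-windowed 3D sinusoidal
grating confined to known grid cells — so classification accuracy *and*
localization can be validated against ground truth without clinical data.

## Worked example

```python
import numpy as np
from hbm3d import (HBMInstanceConfig, HOGParams, PhantomSpec,
                   extract_features, generate_phantom_dataset,
                   localization_score, train_hbm_from_features)
from hbm3d.contribution import contributions_for
from hbm3d.evaluation import run_cv_from_features

spec = PhantomSpec(effect_size=8.0, n_per_class=20, seed=11)
dataset, truth = generate_phantom_dataset(spec)          # 40 subjects, 48^3
params = HOGParams(n_dir2=8, scheme="pole_merged",
                   cell_size=12, overlap_fraction=0.0)   # 64 cells, 26 bins
features = extract_features(dataset, params)
print("descriptors:", features.values.shape)

instance = HBMInstanceConfig.from_preset("KNS26")
report = run_cv_from_features(features, dataset.labels, instance,
                              k=10, n_runs=3, seed=17)
print("pooled accuracy (3-run mean): %.3f" % report.summary["acc"])

model = train_hbm_from_features(features, dataset.labels, instance, seed=17)
c = contributions_for(model.nb, model.training_statuses[0])
top = set(np.argsort(-c)[:len(truth)].tolist())
print("truth cells:", sorted(truth), " top cells:", sorted(top))
print("Jaccard: %.2f" % localization_score(top, truth))
```

Output:

```
descriptors: (40, 64, 26)
pooled accuracy (3-run mean): 0.992
truth cells: [21, 42]  top cells: [21, 42]
Jaccard: 1.00
```

The cohort carries an oriented-texture anomaly (amplitude 8× the noise SD)
in cells 21 and 42 of the 4×4×4 grid. Repeated stratified 10-fold CV
classifies 99% of held-out subjects correctly, and the two cells with the
largest Naive Bayes contributions are exactly the injected anomaly cells.

## Command line

`hbm3d` exposes subcommands `simulate`, `extract`, `train`, `predict`,
`cv`, `scan` and `annotate`, each taking `--config` (YAML), `--seed`,
`--out` and `--verbose`:

```sh
hbm3d simulate --n-per-class 20 --effect-size 8 --seed 11 --out phantoms/
hbm3d cv --labels phantoms/labels.tsv --seed 17 --out cv.json
hbm3d train --labels phantoms/labels.tsv --seed 17 --out model.npz
hbm3d annotate --model model.npz --volume phantoms/asd_000.nii.gz \
    --atlas-volume aal.nii.gz --atlas-table aal.tsv --out regions.tsv
```

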