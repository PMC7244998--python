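"""The two-level classifier: per-cell clustering, regional classifiers,
compact binary representation, and the final SVM.

Training: for every cell independently, the subjects' descriptors are
clustered into k = 2 groups (the binary "status" of that cell — disease- vs
health-related cannot be known a priori, so which cluster is 0 and which is 1
is arbitrary and never canonicalized). A regional classifier per cell
(nearest-centroid for k-means clusters, linear SVM for Ward hierarchical
clusters) reproduces statuses for unseen subjects. Each subject's statuses,
concatenated in raster cell order, form its compact representation; the
final SVM is trained on these against the subject labels.

Prediction: descriptor extraction -> per-cell regional classification ->
compact representation -> final SVM decision score (positive => ASD; a zero
score resolves to HC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.svm import SVC

from .io_core import ASD, HC, BrainVolume, Dataset, INSTANCE_PRESETS, RunConfig
from .hog3d import (
    CellGrid,
    FeatureTensor,
    HOGParams,
    _histograms_for_field,
    compute_gradient_field,
    extract_features,
)
from .contribution import NBModel, fit_nb


class ContractError(ValueError):
    """Mismatch between a model's expectations and the provided input."""


@dataclass
class HBMInstanceConfig:
    """Method choices for one framework instance.

    The named presets pair k-means clustering with nearest-centroid regional
    classifiers (KNS*) and Ward hierarchical clustering with linear-SVM
    regional classifiers (HSS*); the suffix selects the partition scheme
    (32 = full, 26 = pole-merged).
    """

    clustering: str = "kmeans"
    regional: str = "nearest_centroid"
    scheme: str = "pole_merged"
    final_kernel: str = "linear"
    svm_c: float = 1.0
    name: str = "custom"

    @classmethod
    def from_preset(cls, name: str, final_kernel: str = "linear",
                    svm_c: float = 1.0) -> "HBMInstanceConfig":
        if name not in INSTANCE_PRESETS:
            raise ValueError(
                f"unknown instance {name!r}; expected one of "
                f"{sorted(INSTANCE_PRESETS)}"
            )
        clustering, regional, scheme = INSTANCE_PRESETS[name]
        return cls(clustering=clustering, regional=regional, scheme=scheme,
                   final_kernel=final_kernel, svm_c=svm_c, name=name)

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "HBMInstanceConfig":
        return cls(clustering=cfg.clustering, regional=cfg.regional,
                   scheme=cfg.scheme, final_kernel=cfg.final_kernel,
                   svm_c=cfg.svm_c, name=cfg.instance)


@dataclass
class RegionalModel:
    """Per-cell status predictor.

    Either two centroids in descriptor space (``kind="centroid"``), a linear
    hyperplane (``kind="linear"``, weights + bias, status 1 iff
    ``w.x + b > 0``), or a constant (``kind="constant"``) for degenerate
    cells whose training descriptors had fewer than two distinct values.
    """

    cell_index: int
    kind: str  # centroid | linear | constant
    centroids: np.ndarray | None = None  # (2, n_bins), row s = status s
    weights: np.ndarray | None = None
    bias: float = 0.0
    constant_status: int = 0
    degenerate: bool = False

    def predict(self, descriptors: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(descriptors, dtype=float))
        if self.kind == "constant":
            return np.full(len(x), self.constant_status, dtype=np.int8)
        if self.kind == "centroid":
            d0 = np.linalg.norm(x - self.centroids[0], axis=1)
            d1 = np.linalg.norm(x - self.centroids[1], axis=1)
            # equidistant descriptor -> status 0
            return (d1 < d0).astype(np.int8)
        if self.kind == "linear":
            return (x @ self.weights + self.bias > 0).astype(np.int8)
        raise ValueError(f"unknown regional model kind {self.kind!r}")


def fit_cell_clusterers(
    features: FeatureTensor,
    method: str = "kmeans",
    seed: int = 0,
) -> tuple[list[RegionalModel], np.ndarray]:
    """Cluster each cell's descriptors into two statuses.

    For every cell independently, the subjects' descriptors are split into
    two clusters (k-means with k-means++ init, 10 restarts, fixed seed; or
    Ward-linkage hierarchical clustering cut at 2). Returns per-cell cluster
    exemplars packaged as `RegionalModel` seeds (centroids) and the
    subjects x cells status matrix. A cell with fewer than two distinct
    descriptor values gets a constant status-0 model flagged degenerate.
    """
    if features.n_subjects < 2:
        raise ValueError("clustering requires at least 2 training subjects")
    if method not in ("kmeans", "hierarchical"):
        raise ValueError(f"unknown clustering method {method!r}")
    n_subj, n_cells, _ = features.values.shape
    statuses = np.zeros((n_subj, n_cells), dtype=np.int8)
    models: list[RegionalModel] = []
    rng = np.random.SeedSequence(seed)
    cell_seeds = rng.generate_state(n_cells) % (2**31)
    for c in range(n_cells):
        x = features.values[:, c, :]
        if len(np.unique(x, axis=0)) < 2:
            models.append(RegionalModel(cell_index=c, kind="constant",
                                        constant_status=0, degenerate=True))
            continue
        if method == "kmeans":
            km = KMeans(n_clusters=2, init="k-means++", n_init=10,
                        max_iter=300, tol=1e-6,
                        random_state=int(cell_seeds[c]))
            labels = km.fit_predict(x)
            centroids = km.cluster_centers_
        else:
            agg = AgglomerativeClustering(n_clusters=2, linkage="ward")
            labels = agg.fit_predict(x)
            centroids = np.stack([x[labels == s].mean(axis=0)
                                  for s in (0, 1)])
        statuses[:, c] = labels
        models.append(RegionalModel(cell_index=c, kind="centroid",
                                    centroids=centroids))
    return models, statuses


def make_regional_classifier(
    descriptors: np.ndarray,
    statuses: np.ndarray,
    method: str = "nearest_centroid",
    cell_index: int = 0,
    svm_c: float = 1.0,
) -> RegionalModel:
    """Build the test-time status predictor for one cell.

    ``nearest_centroid`` stores the two per-status centroids;
    ``linear_svm`` fits a linear separator (C configurable, default 1) on
    the (descriptor, status) pairs. Single-status cells yield a constant
    model flagged degenerate.
    """
    x = np.asarray(descriptors, dtype=float)
    s = np.asarray(statuses)
    present = np.unique(s)
    if len(present) < 2:
        return RegionalModel(cell_index=cell_index, kind="constant",
                             constant_status=int(present[0]) if len(present)
                             else 0, degenerate=True)
    if method == "nearest_centroid":
        centroids = np.stack([x[s == st].mean(axis=0) for st in (0, 1)])
        return RegionalModel(cell_index=cell_index, kind="centroid",
                             centroids=centroids)
    if method == "linear_svm":
        svm = SVC(kernel="linear", C=svm_c)
        svm.fit(x, s)
        w = svm.coef_.ravel()
        b = float(svm.intercept_[0])
        # SVC orders classes [0, 1]; decision > 0 => class 1
        return RegionalModel(cell_index=cell_index, kind="linear",
                             weights=w, bias=b)
    raise ValueError(f"unknown regional method {method!r}")


def predict_cell_statuses(
    regional_models: list[RegionalModel],
    descriptors: np.ndarray,
) -> np.ndarray:
    """Compact representation of one subject: statuses in raster cell order."""
    x = np.asarray(descriptors, dtype=float)
    if x.ndim != 2 or len(x) != len(regional_models):
        raise ContractError(
            f"expected {len(regional_models)} descriptors, got array of "
            f"shape {x.shape}"
        )
    out = np.empty(len(regional_models), dtype=np.int8)
    for c, model in enumerate(regional_models):
        out[c] = model.predict(x[c][None, :])[0]
    return out


@dataclass
class FinalClassifier:
    """Final SVM over compact representations; positive score => ASD.

    If every training vector is identical the decision degenerates: the
    model then returns a constant score of +1 or -1 for the majority class
    (ties resolve to HC, score -1).
    """

    svm: SVC | None
    constant_score: float | None = None

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.constant_score is not None:
            return np.full(len(x), self.constant_score)
        return self.svm.decision_function(x)


def fit_final_classifier(
    compact: np.ndarray,
    labels: list[str] | np.ndarray,
    kernel: str = "linear",
    svm_c: float = 1.0,
) -> FinalClassifier:
    """Train the final SVM on compact binary vectors.

    Labels are ASD/HC; the decision score is signed with positive meaning
    ASD. Single-class input raises.
    """
    x = np.asarray(compact, dtype=float)
    y = np.asarray([1 if l == ASD else -1 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("final classifier requires both classes present")
    if len(np.unique(x, axis=0)) < 2:
        n_asd = int((y == 1).sum())
        n_hc = int((y == -1).sum())
        return FinalClassifier(svm=None,
                               constant_score=1.0 if n_asd > n_hc else -1.0)
    svm = SVC(kernel=kernel, C=svm_c)
    svm.fit(x, y)
    return FinalClassifier(svm=svm)


@dataclass
class HBMModel:
    """A trained two-level model plus its explanatory Naive Bayes tables."""

    params: HOGParams
    grid: CellGrid
    instance: HBMInstanceConfig
    regional_models: list[RegionalModel]
    final: FinalClassifier
    nb: NBModel
    training_statuses: np.ndarray
    training_labels: list[str]
    affine: np.ndarray
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.grid.n_cells

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for l in self.training_labels:
            counts[l] = counts.get(l, 0) + 1
        return counts


def train_hbm_from_features(
    features: FeatureTensor,
    labels: list[str],
    instance: HBMInstanceConfig,
    seed: int = 0,
    nb_alpha: float = 1.0,
) -> HBMModel:
    """Train the two-level model from precomputed descriptors.

    Feature extraction is label-independent, so cross-validation callers
    extract once and pass fold subsets here; clustering and all classifiers
    are always refit on the training subjects only.
    """
    if len(labels) != features.n_subjects:
        raise ContractError("labels length must match feature tensor")
    _, statuses = fit_cell_clusterers(features, instance.clustering,
                                      seed=seed)
    regional = [
        make_regional_classifier(
            features.values[:, c, :], statuses[:, c],
            method=instance.regional, cell_index=c, svm_c=instance.svm_c,
        )
        for c in range(features.n_cells)
    ]
    # the compact representation feeding the final SVM uses the statuses the
    # regional models will emit, keeping train and test paths identical
    compact = np.stack([
        predict_cell_statuses(regional, features.values[i])
        for i in range(features.n_subjects)
    ])
    final = fit_final_classifier(compact, labels,
                                 kernel=instance.final_kernel,
                                 svm_c=instance.svm_c)
    nb = fit_nb(compact, labels, alpha=nb_alpha)
    return HBMModel(
        params=features.params,
        grid=features.grid,
        instance=instance,
        regional_models=regional,
        final=final,
        nb=nb,
        training_statuses=compact,
        training_labels=list(labels),
        affine=features.affine if features.affine is not None else np.eye(4),
        seed=seed,
    )


def train_hbm(
    dataset: Dataset,
    params: HOGParams,
    instance: HBMInstanceConfig,
    seed: int = 0,
    nb_alpha: float = 1.0,
) -> HBMModel:
    """End-to-end training on a dataset of volumes; deterministic per seed."""
    dataset.require_both_classes()
    features = extract_features(dataset, params)
    return train_hbm_from_features(features, dataset.labels, instance,
                                   seed=seed, nb_alpha=nb_alpha)


def compact_for_volume(model: HBMModel, volume: BrainVolume) -> np.ndarray:
    if tuple(volume.shape) != tuple(model.grid.volume_shape):
        raise ContractError(
            f"volume shape {volume.shape} does not match model grid "
            f"{model.grid.volume_shape}"
        )
    field = compute_gradient_field(volume)
    descriptors = _histograms_for_field(field, model.grid, model.params)
    return predict_cell_statuses(model.regional_models, descriptors)


def predict_subject(
    model: HBMModel, volume: BrainVolume
) -> tuple[str, float, np.ndarray]:
    """Classify one volume: (label, decision score, compact representation).

    The label is ASD iff the final SVM score is strictly positive; a zero
    score resolves to HC.
    """
    compact = compact_for_volume(model, volume)
    score = float(model.final.decision(compact[None, :])[0])
    return (ASD if score > 0 else HC), score, compact


def predict_from_descriptors(
    model: HBMModel, descriptors: np.ndarray
) -> tuple[str, float, np.ndarray]:
    """As `predict_subject` but from a precomputed (cells x bins) matrix."""
    compact = predict_cell_statuses(model.regional_models, descriptors)
    score = float(model.final.decision(compact[None, :])[0])
    return (ASD if score > 0 else HC), score, compact


# --- model archive ----------------------------------------------------------

def save_model(model: HBMModel, path: str | Path) -> None:
    """Serialize to a single .npz archive (JSON metadata + array payloads)."""
    arrays: dict[str, np.ndarray] = {
        "grid_origins": model.grid.origins,
        "training_statuses": model.training_statuses,
        "affine": model.affine,
        "nb_priors": np.array([model.nb.prior_d, model.nb.prior_h]),
        "nb_p1": model.nb.p1,  # (2, n_cells): P(X_i=1 | D), P(X_i=1 | H)
    }
    reg_meta = []
    for m in model.regional_models:
        reg_meta.append(dict(kind=m.kind, constant_status=m.constant_status,
                             degenerate=m.degenerate, bias=m.bias))
        if m.kind == "centroid":
            arrays[f"reg_{m.cell_index}_centroids"] = m.centroids
        elif m.kind == "linear":
            arrays[f"reg_{m.cell_index}_weights"] = m.weights
    if model.final.svm is not None:
        arrays["final_support"] = model.final.svm.support_vectors_
        arrays["final_dual"] = model.final.svm.dual_coef_
        arrays["final_intercept"] = model.final.svm.intercept_
    meta = dict(
        params=dict(
            n_dir2=model.params.n_dir2, scheme=model.params.scheme,
            cell_size=model.params.cell_size,
            overlap_fraction=model.params.overlap_fraction,
            normalize=model.params.normalize,
        ),
        grid=dict(volume_shape=list(model.grid.volume_shape),
                  cell_shape=list(model.grid.cell_shape),
                  stride=list(model.grid.stride),
                  masked=model.grid.masked),
        instance=dict(clustering=model.instance.clustering,
                      regional=model.instance.regional,
                      scheme=model.instance.scheme,
                      final_kernel=model.instance.final_kernel,
                      svm_c=model.instance.svm_c,
                      name=model.instance.name),
        regional=reg_meta,
        final_constant=model.final.constant_score,
        final_gamma=(None if model.final.svm is None
                     else float(model.final.svm._gamma)),
        nb_alpha=model.nb.alpha,
        training_labels=model.training_labels,
        seed=model.seed,
        class_counts=model.class_counts(),
    )
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(str(path), **arrays)


def load_model(path: str | Path) -> HBMModel:
    data = np.load(str(path), allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    params = HOGParams(**meta["params"])
    grid = CellGrid(
        volume_shape=tuple(meta["grid"]["volume_shape"]),
        cell_shape=tuple(meta["grid"]["cell_shape"]),
        stride=tuple(meta["grid"]["stride"]),
        origins=data["grid_origins"],
        masked=meta["grid"].get("masked", False),
    )
    instance = HBMInstanceConfig(**meta["instance"])
    regional = []
    for c, rm in enumerate(meta["regional"]):
        model = RegionalModel(cell_index=c, kind=rm["kind"],
                              constant_status=rm["constant_status"],
                              degenerate=rm["degenerate"], bias=rm["bias"])
        if rm["kind"] == "centroid":
            model.centroids = data[f"reg_{c}_centroids"]
        elif rm["kind"] == "linear":
            model.weights = data[f"reg_{c}_weights"]
        regional.append(model)
    if meta["final_constant"] is not None:
        final = FinalClassifier(svm=None,
                                constant_score=meta["final_constant"])
    else:
        training = data["training_statuses"].astype(float)
        labels = meta["training_labels"]
        final = fit_final_classifier(training, labels,
                                     kernel=instance.final_kernel,
                                     svm_c=instance.svm_c)
    nb = NBModel(prior_d=float(data["nb_priors"][0]),
                 prior_h=float(data["nb_priors"][1]),
                 p1=data["nb_p1"], alpha=float(meta["nb_alpha"]))
    return HBMModel(
        params=params, grid=grid, instance=instance,
        regional_models=regional, final=final, nb=nb,
        training_statuses=data["training_statuses"],
        training_labels=list(meta["training_labels"]),
        affine=data["affine"], seed=int(meta["seed"]),
    )
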