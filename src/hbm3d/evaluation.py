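"""Stratified k-fold cross-validation with multiple random runs, the metric
panel, and the cell-size x overlap parameter scan.

Each run reshuffles subjects (run-specific seed derived from the master
seed), deals each class round-robin into k folds so per-class fold counts
differ by at most one, trains on k-1 folds and scores the held-out fold.
Held-out predictions are pooled within a run — the pooled confusion counts
sum to the dataset size — and pooled metrics are averaged across runs.
Feature extraction is label-independent and computed once per dataset;
clustering and all classifiers are refit per fold to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_core import ASD, HC, Dataset
from .hog3d import FeatureTensor, HOGParams, extract_features
from .hbm import HBMInstanceConfig, predict_cell_statuses, train_hbm_from_features


@dataclass
class ConfusionCounts:
    """2x2 counts with ASD as the positive class."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_pairs(cls, truth, predicted) -> "ConfusionCounts":
        truth = list(truth)
        predicted = list(predicted)
        if len(truth) != len(predicted):
            raise ValueError("truth and prediction lists differ in length")
        c = cls()
        for t, p in zip(truth, predicted):
            if t == ASD:
                if p == ASD:
                    c.tp += 1
                else:
                    c.fn += 1
            else:
                if p == ASD:
                    c.fp += 1
                else:
                    c.tn += 1
        return c


def _ratio(num: int, den: int) -> float:
    """Ratios with zero denominators are undefined (NaN), never 0 by fiat."""
    return num / den if den > 0 else float("nan")


@dataclass
class Metrics:
    """The standard panel: ACC, SEN, SPE, PPV, NPV, F1 and rank-based AUC."""

    counts: ConfusionCounts
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    f1: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return dict(acc=self.acc, sen=self.sen, spe=self.spe, ppv=self.ppv,
                    npv=self.npv, f1=self.f1, auc=self.auc,
                    tp=self.counts.tp, fn=self.counts.fn,
                    tn=self.counts.tn, fp=self.counts.fp)


def rank_auc(scores, truth) -> float:
    """Probability a random ASD score exceeds a random HC score; ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    is_pos = np.asarray([t == ASD for t in truth])
    n_pos = int(is_pos.sum())
    n_neg = int(len(is_pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compute_metrics(counts: ConfusionCounts,
                    scores: list[tuple[float, str]] | None = None) -> Metrics:
    """Full metric panel from confusion counts and optional (score, truth)
    pairs for the AUC."""
    c = counts
    acc = _ratio(c.tp + c.tn, c.total)
    sen = _ratio(c.tp, c.tp + c.fn)
    spe = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    if np.isnan(ppv) or np.isnan(sen) or (ppv + sen) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * ppv * sen / (ppv + sen)
    auc = float("nan")
    if scores is not None:
        auc = rank_auc([s for s, _ in scores], [t for _, t in scores])
    return Metrics(counts=c, acc=acc, sen=sen, spe=spe, ppv=ppv, npv=npv,
                   f1=f1, auc=auc)


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: shuffle within class, deal round-robin.

    Per-class per-fold counts differ by at most one, keeping each fold's
    class ratio as close as possible to the full dataset's.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = list(labels)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} subjects")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in sorted(set(labels)):
        idx = np.flatnonzero([l == cls for l in labels])
        rng.shuffle(idx)
        for pos, subject in enumerate(idx):
            assignment[subject] = pos % k
    return assignment


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    truth: list[str]
    predictions: list[str]
    scores: np.ndarray
    metrics: Metrics


@dataclass
class RunResult:
    run: int
    seed: int
    folds: list[FoldResult]
    pooled: Metrics


@dataclass
class CVReport:
    """All per-run / per-fold metrics plus the run-averaged summary."""

    runs: list[RunResult]
    summary: dict[str, float]
    fold_averaged: dict[str, float]
    config: dict = field(default_factory=dict)
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dict(
            master_seed=self.master_seed,
            config=self.config,
            summary=self.summary,
            fold_averaged=self.fold_averaged,
            runs=[
                dict(
                    run=r.run,
                    seed=r.seed,
                    pooled=r.pooled.as_dict(),
                    folds=[
                        dict(fold=f.fold,
                             test_indices=f.test_indices.tolist(),
                             truth=f.truth,
                             predictions=f.predictions,
                             scores=f.scores.tolist(),
                             metrics=f.metrics.as_dict())
                        for f in r.folds
                    ],
                )
                for r in self.runs
            ],
        )


def _run_seed(master_seed: int, run: int) -> int:
    return int(np.random.SeedSequence([master_seed, run])
               .generate_state(1)[0] % (2**31))


_METRIC_KEYS = ("acc", "sen", "spe", "ppv", "npv", "f1", "auc")


def run_cv_from_features(
    features: FeatureTensor,
    labels: list[str],
    instance: HBMInstanceConfig,
    k: int = 10,
    n_runs: int = 10,
    seed: int = 20200508,
    nb_alpha: float = 1.0,
) -> CVReport:
    """Repeated stratified k-fold CV on precomputed descriptors."""
    labels = list(labels)
    runs: list[RunResult] = []
    for r in range(n_runs):
        rs = _run_seed(seed, r)
        assignment = stratified_folds(labels, k, rs)
        folds: list[FoldResult] = []
        pooled_truth: list[str] = []
        pooled_pred: list[str] = []
        pooled_scores: list[float] = []
        for f in range(k):
            test_idx = np.flatnonzero(assignment == f)
            if len(test_idx) == 0:
                continue
            train_idx = np.flatnonzero(assignment != f)
            train_labels = [labels[i] for i in train_idx]
            model = train_hbm_from_features(
                features.subset(train_idx), train_labels, instance,
                seed=rs + f, nb_alpha=nb_alpha,
            )
            preds, scores = [], []
            for i in test_idx:
                compact = predict_cell_statuses(model.regional_models,
                                                features.values[i])
                score = float(model.final.decision(compact[None, :])[0])
                preds.append(ASD if score > 0 else HC)
                scores.append(score)
            truth = [labels[i] for i in test_idx]
            counts = ConfusionCounts.from_pairs(truth, preds)
            fold_metrics = compute_metrics(
                counts, list(zip(scores, truth)))
            folds.append(FoldResult(fold=f, test_indices=test_idx,
                                    truth=truth, predictions=preds,
                                    scores=np.asarray(scores),
                                    metrics=fold_metrics))
            pooled_truth.extend(truth)
            pooled_pred.extend(preds)
            pooled_scores.extend(scores)
        pooled_counts = ConfusionCounts.from_pairs(pooled_truth, pooled_pred)
        pooled = compute_metrics(pooled_counts,
                                 list(zip(pooled_scores, pooled_truth)))
        runs.append(RunResult(run=r, seed=rs, folds=folds, pooled=pooled))

    summary = {
        key: float(np.mean([getattr(r.pooled, key) for r in runs]))
        for key in _METRIC_KEYS
    }
    with np.errstate(invalid="ignore"):
        fold_averaged = {
            key: float(np.nanmean([
                getattr(f.metrics, key) for r in runs for f in r.folds
            ]))
            for key in _METRIC_KEYS
        }
    return CVReport(
        runs=runs, summary=summary, fold_averaged=fold_averaged,
        config=dict(k=k, n_runs=n_runs, instance=instance.name,
                    clustering=instance.clustering,
                    regional=instance.regional, scheme=instance.scheme,
                    final_kernel=instance.final_kernel),
        master_seed=seed,
    )


def run_cv(
    dataset: Dataset,
    params: HOGParams,
    instance: HBMInstanceConfig,
    k: int = 10,
    n_runs: int = 10,
    seed: int = 20200508,
    nb_alpha: float = 1.0,
) -> CVReport:
    """Repeated stratified k-fold CV on a dataset of volumes.

    Descriptors are extracted once (they do not depend on labels) and every
    model component is refit inside each training fold.
    """
    dataset.require_both_classes()
    features = extract_features(dataset, params)
    return run_cv_from_features(features, dataset.labels, instance, k=k,
                                n_runs=n_runs, seed=seed, nb_alpha=nb_alpha)


@dataclass
class ScanResult:
    """Accuracy grid over (cell size, overlap) with its argmax."""

    cell_sizes: list[int]
    overlaps: list[float]
    accuracy: np.ndarray  # (len(cell_sizes), len(overlaps))
    best_cell_size: int
    best_overlap: float
    reports: dict[tuple[int, float], CVReport]


def parameter_scan(
    dataset: Dataset,
    cell_sizes: list[int],
    overlaps: list[float],
    instance: HBMInstanceConfig,
    base_params: HOGParams | None = None,
    k: int = 10,
    n_runs: int = 3,
    seed: int = 20200508,
) -> ScanResult:
    """Cross-validated accuracy over the cell-size x overlap grid.

    The reported best pair is the grid argmax of run-averaged pooled
    accuracy; ties resolve to the smallest cell size, then smallest overlap.
    """
    if not cell_sizes or not overlaps:
        raise ValueError("cell_sizes and overlaps must be nonempty")
    base = base_params or HOGParams()
    acc = np.empty((len(cell_sizes), len(overlaps)))
    reports: dict[tuple[int, float], CVReport] = {}
    for i, size in enumerate(cell_sizes):
        for j, ov in enumerate(overlaps):
            params = HOGParams(n_dir2=base.n_dir2, scheme=base.scheme,
                               cell_size=size, overlap_fraction=ov,
                               normalize=base.normalize)
            report = run_cv(dataset, params, instance, k=k, n_runs=n_runs,
                            seed=seed)
            acc[i, j] = report.summary["acc"]
            reports[(size, ov)] = report
    best_flat = int(np.argmax(acc))  # argmax returns the first (smallest) tie
    bi, bj = np.unravel_index(best_flat, acc.shape)
    return ScanResult(
        cell_sizes=list(cell_sizes), overlaps=list(overlaps), accuracy=acc,
        best_cell_size=int(cell_sizes[bi]), best_overlap=float(overlaps[bj]),
        reports=reports,
    )
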