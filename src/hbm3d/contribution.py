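"""Naive Bayes feature contributions and MNI-space atlas annotation.

Over compact status vectors x = (x_0, ..., x_n), a Naive Bayes model with
class variable Y in {D, H} (disease / healthy) assumes the per-cell statuses
are conditionally independent given Y. The posterior log-odds decomposes as

    log P(D | x) / P(H | x) = log P(D) / P(H) + sum_i c(i, x_i)

where c(i, s) = log P(X_i = s | D) - log P(X_i = s | H) is the *feature
contribution* of cell i in state s. Because the cluster identity of a cell
status is arbitrary, contributions are evaluated for both states; a larger
value marks a more disease-predictive cell. Cells whose contribution for a
given subject exceeds a threshold are annotated with atlas region names in
MNI millimetre space (cell centers mapped through the NIfTI affine; centers
landing on atlas background are assigned the nearest labeled voxel).

The Naive Bayes model is an explanatory companion: the SVM remains the
deciding classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ASD, AtlasVolume
from .hog3d import CellGrid


class ContractError(ValueError):
    pass


@dataclass
class NBModel:
    """Class priors and per-cell Bernoulli conditionals with smoothing.

    ``p1[0, i] = P(X_i = 1 | D)`` and ``p1[1, i] = P(X_i = 1 | H)``;
    ``P(X_i = 0 | Y) = 1 - P(X_i = 1 | Y)`` by construction. ``alpha`` is the
    Laplace smoothing constant, which keeps every probability inside (0, 1)
    and every log finite.
    """

    prior_d: float
    prior_h: float
    p1: np.ndarray  # (2, n_cells)
    alpha: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.p1.shape[1]

    def conditional(self, i: int, s: int, y: str) -> float:
        row = 0 if y == ASD else 1
        p = self.p1[row, i]
        return float(p if s == 1 else 1.0 - p)


def fit_nb(compact: np.ndarray, labels, alpha: float = 1.0) -> NBModel:
    """Fit priors and smoothed conditionals from compact representations.

    Priors are raw class frequencies; conditionals use add-alpha smoothing,
    ``P(X_i = 1 | Y) = (count_1 + alpha) / (n_Y + 2 alpha)``.
    """
    if alpha <= 0:
        raise ValueError("smoothing constant alpha must be > 0")
    x = np.asarray(compact)
    y = np.asarray([1 if l == ASD else 0 for l in labels])
    n_d = int(y.sum())
    n_h = int(len(y) - n_d)
    if n_d == 0 or n_h == 0:
        raise ValueError("Naive Bayes requires both classes present")
    p1 = np.empty((2, x.shape[1]))
    p1[0] = (x[y == 1].sum(axis=0) + alpha) / (n_d + 2 * alpha)
    p1[1] = (x[y == 0].sum(axis=0) + alpha) / (n_h + 2 * alpha)
    return NBModel(prior_d=n_d / len(y), prior_h=n_h / len(y),
                   p1=p1, alpha=alpha)


def feature_contribution(nb: NBModel, i: int, s: int) -> float:
    """c(i, s) = log P(X_i = s | D) - log P(X_i = s | H)."""
    if not (0 <= i < nb.n_cells):
        raise ContractError(f"cell index {i} out of range [0, {nb.n_cells})")
    if s not in (0, 1):
        raise ContractError("status must be 0 or 1")
    return float(np.log(nb.conditional(i, s, ASD))
                 - np.log(nb.conditional(i, s, "HC")))


def contributions_for(nb: NBModel, x: np.ndarray) -> np.ndarray:
    """Vector of c(i, x_i) over all cells for one subject's statuses."""
    x = np.asarray(x)
    if x.shape != (nb.n_cells,):
        raise ContractError(
            f"status vector length {x.shape} does not match {nb.n_cells} cells"
        )
    p_d = np.where(x == 1, nb.p1[0], 1.0 - nb.p1[0])
    p_h = np.where(x == 1, nb.p1[1], 1.0 - nb.p1[1])
    return np.log(p_d) - np.log(p_h)


def log_posterior_ratio(nb: NBModel, x: np.ndarray) -> float:
    """log P(D | x) / P(H | x); positive means ASD is the more likely class."""
    c = contributions_for(nb, x)
    return float(np.log(nb.prior_d) - np.log(nb.prior_h) + c.sum())


@dataclass
class ContributionMap:
    """Per-cell contributions c(i, x_i) for one subject, with a threshold."""

    contributions: np.ndarray
    statuses: np.ndarray
    threshold: float


def default_threshold(contributions: np.ndarray, percentile: float = 95.0
                      ) -> float:
    """Scale-free default: a percentile of the subject's own contributions."""
    return float(np.percentile(np.asarray(contributions), percentile))


def select_predictive_cells(
    nb: NBModel, x: np.ndarray, threshold: float
) -> list[tuple[int, float]]:
    """Cells with c(i, x_i) > threshold, sorted by descending contribution.

    Ties order by ascending cell index, deterministically.
    """
    c = contributions_for(nb, x)
    above = np.flatnonzero(c > threshold)
    order = sorted(above.tolist(), key=lambda i: (-c[i], i))
    return [(int(i), float(c[i])) for i in order]


def voxel_to_mni(voxel: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Apply the voxel->MNI affine in homogeneous coordinates.

    Accepts one coordinate triple or an (n, 3) array.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    v = np.atleast_2d(np.asarray(voxel, dtype=float))
    out = v @ affine[:3, :3].T + affine[:3, 3]
    return out[0] if np.asarray(voxel).ndim == 1 else out


@dataclass
class RegionAnnotation:
    """One predictive cell located in the atlas."""

    cell_index: int
    center_voxel: np.ndarray
    center_mni: np.ndarray
    region: str
    contribution: float


def _nearest_labeled(atlas: AtlasVolume, point_mm: np.ndarray) -> int:
    """Code of the labeled atlas voxel nearest in millimetres.

    Distance ties resolve to the smallest code, then the first voxel in scan
    order.
    """
    labeled = np.argwhere(atlas.codes != 0)
    if len(labeled) == 0:
        raise ValueError("atlas contains no labeled voxels")
    mm = voxel_to_mni(labeled.astype(float), atlas.affine)
    d2 = np.sum((mm - point_mm) ** 2, axis=1)
    dmin = d2.min()
    tied = np.flatnonzero(d2 <= dmin + 1e-9)
    codes = atlas.codes[tuple(labeled[tied].T)]
    return int(codes.min())


def annotate_cells(
    selected: list[tuple[int, float]],
    grid: CellGrid,
    affine: np.ndarray,
    atlas: AtlasVolume,
) -> list[RegionAnnotation]:
    """Name the atlas region under each selected cell's center.

    The cell center (origin + (extent - 1) / 2 per axis) is mapped through
    the volume affine into MNI mm, then into atlas voxel space. A center
    landing on a labeled voxel takes that region; a center on background (or
    outside the atlas grid) takes the nearest labeled voxel by Euclidean mm
    distance, ties to the smallest code.
    """
    if not np.any(atlas.codes != 0):
        raise ValueError("atlas contains no labeled voxels")
    inv = np.linalg.inv(atlas.affine)
    centers = grid.centers_voxel()
    out: list[RegionAnnotation] = []
    for cell, contrib in selected:
        center_vox = centers[cell]
        mni = voxel_to_mni(center_vox, affine)
        atlas_vox = np.rint(voxel_to_mni(mni, inv)).astype(int)
        code = 0
        if all(0 <= atlas_vox[k] < atlas.codes.shape[k] for k in range(3)):
            code = int(atlas.codes[tuple(atlas_vox)])
        if code == 0:
            code = _nearest_labeled(atlas, mni)
        out.append(RegionAnnotation(
            cell_index=int(cell),
            center_voxel=center_vox,
            center_mni=np.asarray(mni, dtype=float),
            region=atlas.names[code],
            contribution=float(contrib),
        ))
    return out


def annotations_to_frame(annotations: list[RegionAnnotation]) -> pd.DataFrame:
    """Tabulate annotations (one row per cell, TSV-ready)."""
    return pd.DataFrame([
        dict(
            cell_index=a.cell_index,
            vox_x=a.center_voxel[0], vox_y=a.center_voxel[1],
            vox_z=a.center_voxel[2],
            mni_x=a.center_mni[0], mni_y=a.center_mni[1],
            mni_z=a.center_mni[2],
            region=a.region,
            contribution=a.contribution,
        )
        for a in annotations
    ])
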