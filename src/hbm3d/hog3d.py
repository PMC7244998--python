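"""3D histograms of oriented gradients over an overlapping cell grid.

A gradient direction in 3D is described by two angles: the azimuth ``theta``
(degrees in ``[0, 360)``, measured from +x toward +y in the xy-plane) and the
polar angle ``phi`` (degrees in ``[0, 180]``, measured from the +z axis). The
sphere of directions is discretized under one of two partition schemes, both
parameterized by an even 2D direction count ``n_dir2``:

``full``
    Equal-angle azimuth sectors times equal-angle polar bands, like
    latitude/longitude patches: ``n_dir2`` sectors x ``n_dir2 / 2`` bands,
    giving ``n_dir2**2 / 2`` bins (32 for ``n_dir2 = 8``).

``pole_merged``
    The patches touching each pole are merged into a single cap bin (a small
    azimuth change near a pole should not flip the bin). Caps have polar
    half-width ``180 / n_dir2`` degrees; the remaining band is split into
    ``n_dir2 / 2 - 1`` equal polar bands x ``n_dir2`` sectors, giving
    ``n_dir2 * (n_dir2 / 2 - 1) + 2`` bins (26 for ``n_dir2 = 8``).

Each voxel votes its gradient magnitude into the bin of its direction (hard
assignment); per-cell descriptors are L2-normalized by default. A slice-wise
2D baseline (`extract_features_2d`) bins in-plane gradients into ``n_dir2``
equal sectors over 360 degrees and feeds each (slice, square-cell) pair into
the identical downstream pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import BrainVolume, Dataset, GeometryError

_EPS = 1e-12


class ParameterError(ValueError):
    pass


def bin_count(n_dir2: int, scheme: str) -> int:
    """Number of 3D orientation bins for a partition scheme.

    ``full``: ``n_dir2**2 / 2``; ``pole_merged``:
    ``n_dir2 * (n_dir2 / 2 - 1) + 2``. ``n_dir2`` must be even and >= 2.
    """
    if n_dir2 < 2 or n_dir2 % 2 != 0:
        raise ParameterError(f"n_dir2 must be an even integer >= 2, got {n_dir2}")
    if scheme == "full":
        return n_dir2 * n_dir2 // 2
    if scheme == "pole_merged":
        return n_dir2 * (n_dir2 // 2 - 1) + 2
    raise ParameterError(f"unknown partition scheme {scheme!r}")


@dataclass
class HOGParams:
    """Descriptor parameters: direction count, scheme, cell geometry."""

    n_dir2: int = 8
    scheme: str = "pole_merged"
    cell_size: int = 14
    overlap_fraction: float = 0.5
    normalize: bool = True

    def __post_init__(self) -> None:
        self.n_dir3 = bin_count(self.n_dir2, self.scheme)  # validates n_dir2
        if self.cell_size < 2:
            raise ParameterError("cell_size must be >= 2 voxels")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ParameterError("overlap_fraction must be in [0, 1)")


@dataclass
class GradientField:
    """Per-voxel gradient magnitude and direction angles (degrees).

    ``theta`` is the azimuth in ``[0, 360)``, ``phi`` the polar angle from +z
    in ``[0, 180]``. Zero-magnitude voxels carry the conventional direction
    ``(theta, phi) = (0, 90)``; they cast zero-weight votes so the convention
    never influences a histogram.
    """

    magnitude: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.magnitude.shape


def _derivative(data: np.ndarray, axis: int) -> np.ndarray:
    # central difference (f[i+1] - f[i-1]) / 2 with replicated edges
    return ndimage.correlate1d(
        np.asarray(data, dtype=float), [-0.5, 0.0, 0.5], axis=axis,
        mode="nearest",
    )


def compute_gradient_field(volume: BrainVolume | np.ndarray) -> GradientField:
    """Central-difference gradients with replicated borders, as angles.

    Interior voxels use ``(f[i+1] - f[i-1]) / 2``; border voxels replicate the
    edge value, which reduces to a halved one-sided difference.
    """
    data = volume.intensities if isinstance(volume, BrainVolume) else volume
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    gx = _derivative(data, 0)
    gy = _derivative(data, 1)
    gz = _derivative(data, 2)
    magnitude = np.sqrt(gx * gx + gy * gy + gz * gz)
    zero = magnitude < _EPS
    theta = np.degrees(np.arctan2(gy, gx))
    theta = np.where(theta < 0.0, theta + 360.0, theta)
    theta = np.where(theta >= 360.0, 0.0, theta)  # guard -0.0 wrap
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.degrees(np.arccos(np.clip(
            np.divide(gz, magnitude, out=np.zeros_like(gz), where=~zero),
            -1.0, 1.0,
        )))
    theta = np.where(zero, 0.0, theta)
    phi = np.where(zero, 90.0, phi)
    return GradientField(magnitude=magnitude, theta=theta, phi=phi)


def assign_orientation_bin(
    theta: np.ndarray | float, phi: np.ndarray | float, params: HOGParams
) -> np.ndarray | int:
    """Map direction angles to a bin index in ``[0, n_dir3)``.

    Intervals are half-open on the upper side except the closing boundary
    (``phi = 180`` falls in the last polar band / south cap; ``theta`` wraps
    at 360 so no closing case arises azimuthally).

    ``full``: index = band * n_dir2 + sector, with
    ``sector = floor(theta / (360 / n_dir2))`` and
    ``band = min(floor(phi / (180 / (n_dir2 / 2))), n_dir2 / 2 - 1)``.

    ``pole_merged``: bin 0 is the north cap (``phi < 180 / n_dir2``), bin
    ``n_dir3 - 1`` the south cap (``phi >= 180 - 180 / n_dir2``); between
    them ``n_dir2 / 2 - 1`` equal polar bands x ``n_dir2`` sectors, indexed
    ``1 + band * n_dir2 + sector``.
    """
    theta_a = np.asarray(theta, dtype=float)
    phi_a = np.asarray(phi, dtype=float)
    scalar = theta_a.ndim == 0 and phi_a.ndim == 0
    if np.any(theta_a < 0) or np.any(theta_a >= 360):
        raise ValueError("theta out of range [0, 360)")
    if np.any(phi_a < 0) or np.any(phi_a > 180):
        raise ValueError("phi out of range [0, 180]")

    n2 = params.n_dir2
    sector = np.floor(theta_a / (360.0 / n2)).astype(np.int64)
    sector = np.minimum(sector, n2 - 1)  # float roundoff guard

    if params.scheme == "full":
        n_bands = n2 // 2
        band = np.floor(phi_a / (180.0 / n_bands)).astype(np.int64)
        band = np.minimum(band, n_bands - 1)
        index = band * n2 + sector
    else:
        cap = 180.0 / n2
        n_mid = n2 // 2 - 1
        north = phi_a < cap
        south = phi_a >= 180.0 - cap
        if n_mid == 0:
            # degenerate: the two caps tile the sphere (phi = 90 -> south)
            index = np.where(phi_a < 90.0, 0, 1).astype(np.int64)
        else:
            band = np.floor((phi_a - cap) / ((180.0 - 2 * cap) / n_mid))
            band = np.clip(band, 0, n_mid - 1).astype(np.int64)
            index = 1 + band * n2 + sector
            index = np.where(north, 0, index)
            index = np.where(south, params.n_dir3 - 1, index)
    return int(index) if scalar else index


@dataclass
class CellGrid:
    """Raster-ordered overlapping cell grid over a fixed volume shape.

    ``origins`` enumerate cell origins with the first axis fastest, i.e.
    raster order of ``itertools.product`` over (z, y, x) reversed — here:
    x fastest, then y, then z. Every cell lies fully inside the volume.
    ``cell_shape`` is the 3D cell extent; cubic for 3D HOG, flat (extent 1
    along the slicing axis) for the 2D slice baseline.
    """

    volume_shape: tuple[int, int, int]
    cell_shape: tuple[int, int, int]
    stride: tuple[int, int, int]
    origins: np.ndarray  # (n_cells, 3) int
    masked: bool = False  # True if a brain mask dropped low-coverage cells

    @property
    def n_cells(self) -> int:
        return len(self.origins)

    @property
    def cell_size(self) -> int:
        return int(max(self.cell_shape))

    def centers_voxel(self) -> np.ndarray:
        """Cell centers in voxel coordinates: origin + (extent - 1) / 2."""
        ext = np.asarray(self.cell_shape, dtype=float)
        return self.origins + (ext - 1.0) / 2.0


def _axis_origins(extent: int, size: int, stride: int) -> np.ndarray:
    n = (extent - size) // stride + 1
    return np.arange(n) * stride


def make_cell_grid(
    volume_shape: tuple[int, int, int],
    cell_size: int,
    overlap_fraction: float,
    mask: np.ndarray | None = None,
) -> CellGrid:
    """Build the overlapping cubic cell grid.

    Stride is ``max(1, round(cell_size * (1 - overlap_fraction)))``; per axis,
    origins run 0, stride, 2*stride, ... while the cell still fits. With an
    optional boolean brain mask, cells with fewer than 50% in-mask voxels are
    dropped (the remaining raster order is preserved).
    """
    shape = tuple(int(s) for s in volume_shape)
    if any(cell_size > s for s in shape):
        raise GeometryError(
            f"cell_size {cell_size} exceeds volume extent {shape}"
        )
    stride = max(1, round(cell_size * (1.0 - overlap_fraction)))
    ax = [_axis_origins(s, cell_size, stride) for s in shape]
    # x fastest: meshgrid with ij indexing over (z, y, x) then reverse columns
    zz, yy, xx = np.meshgrid(ax[2], ax[1], ax[0], indexing="ij")
    origins = np.stack(
        [xx.ravel(), yy.ravel(), zz.ravel()], axis=1
    ).astype(np.int64)
    masked = False
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise GeometryError("mask shape must match volume shape")
        keep = []
        for origin in origins:
            sl = tuple(slice(int(o), int(o) + cell_size) for o in origin)
            keep.append(mask[sl].mean() >= 0.5)
        origins = origins[np.asarray(keep)]
        masked = True
        if len(origins) == 0:
            raise GeometryError("mask removed every cell from the grid")
    return CellGrid(
        volume_shape=shape,
        cell_shape=(cell_size, cell_size, cell_size),
        stride=(stride, stride, stride),
        origins=origins,
        masked=masked,
    )


def cell_histogram(
    field: GradientField,
    origin: tuple[int, int, int],
    params: HOGParams,
    cell_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Magnitude-weighted orientation histogram of one cell.

    Each voxel casts a vote of weight equal to its gradient magnitude into
    its orientation bin. With ``params.normalize`` the descriptor is divided
    by its Euclidean norm, unless the norm is below 1e-12 (left all-zero).
    """
    shape = cell_shape or params_cell_shape(params)
    sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
    for o, s, ext in zip(origin, shape, field.shape):
        if o < 0 or o + s > ext:
            raise GeometryError(
                f"cell at origin {tuple(origin)} with shape {shape} exceeds "
                f"field extents {field.shape}"
            )
    bins = assign_orientation_bin(field.theta[sl], field.phi[sl], params)
    hist = np.bincount(
        np.ravel(bins), weights=np.ravel(field.magnitude[sl]),
        minlength=params.n_dir3,
    )
    if params.normalize:
        norm = np.linalg.norm(hist)
        if norm >= _EPS:
            hist = hist / norm
    return hist


def params_cell_shape(params: HOGParams) -> tuple[int, int, int]:
    return (params.cell_size, params.cell_size, params.cell_size)


@dataclass
class FeatureTensor:
    """Per-subject, per-cell orientation histograms plus their geometry."""

    values: np.ndarray  # (n_subjects, n_cells, n_bins)
    grid: CellGrid
    params: HOGParams
    subject_ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    affine: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "FeatureTensor":
        idx = np.asarray(idx)
        return FeatureTensor(
            values=self.values[idx],
            grid=self.grid,
            params=self.params,
            subject_ids=[self.subject_ids[i] for i in idx]
            if self.subject_ids else [],
            labels=[self.labels[i] for i in idx] if self.labels else [],
            affine=self.affine,
        )


def _histograms_for_field(
    field: GradientField, grid: CellGrid, params: HOGParams
) -> np.ndarray:
    """All per-cell histograms of one gradient field.

    Bins are precomputed once per volume; each cell then reduces its slice
    with a weighted bincount.
    """
    bins = assign_orientation_bin(field.theta, field.phi, params)
    out = np.empty((grid.n_cells, params.n_dir3))
    for c, origin in enumerate(grid.origins):
        sl = tuple(
            slice(int(o), int(o) + s) for o, s in zip(origin, grid.cell_shape)
        )
        hist = np.bincount(
            np.ravel(bins[sl]), weights=np.ravel(field.magnitude[sl]),
            minlength=params.n_dir3,
        )
        if params.normalize:
            norm = np.linalg.norm(hist)
            if norm >= _EPS:
                hist = hist / norm
        out[c] = hist
    return out


def extract_features(dataset: Dataset, params: HOGParams,
                     mask: np.ndarray | None = None) -> FeatureTensor:
    """3D HOG descriptors for every subject on the shared cell grid.

    The grid is built once from the shared volume shape, so the cell order
    (raster order) is identical for every subject; this order is the single
    source of truth for the compact representation downstream. An optional
    boolean brain mask drops cells with under 50% in-mask voxels.
    """
    grid = make_cell_grid(dataset.shape, params.cell_size,
                          params.overlap_fraction, mask=mask)
    values = np.empty((len(dataset), grid.n_cells, params.n_dir3))
    for i, vol in enumerate(dataset):
        field_ = compute_gradient_field(vol)
        values[i] = _histograms_for_field(field_, grid, params)
    return FeatureTensor(
        values=values,
        grid=grid,
        params=params,
        subject_ids=[v.subject_id for v in dataset],
        labels=[v.label for v in dataset],
        affine=dataset.affine.copy(),
    )


def extract_features_2d(
    dataset: Dataset, slicing_axis: int = 2, params: HOGParams | None = None
) -> FeatureTensor:
    """Slice-wise 2D HOG baseline on the same overlapping-cell geometry.

    Gradients are in-plane central differences per slice; directions are
    binned into ``n_dir2`` equal sectors over 360 degrees. Cells are squares
    of ``cell_size`` with the same stride rule, and every (slice, 2D-cell)
    pair becomes one cell of the output tensor, so the downstream clustering /
    classification pipeline runs unchanged.
    """
    params = params or HOGParams()
    shape = dataset.shape
    in_plane = [ax for ax in range(3) if ax != slicing_axis]
    if any(params.cell_size > shape[ax] for ax in in_plane):
        raise GeometryError(
            f"cell_size {params.cell_size} exceeds in-plane extents"
        )
    stride = max(1, round(params.cell_size * (1.0 - params.overlap_fraction)))
    ax_origins = {
        ax: _axis_origins(shape[ax], params.cell_size, stride)
        for ax in in_plane
    }
    slices = np.arange(shape[slicing_axis])

    # raster order: first axis fastest among (x, y, z) restricted to the grid
    coords: dict[int, np.ndarray] = {slicing_axis: slices}
    coords.update(ax_origins)
    zz, yy, xx = np.meshgrid(coords[2], coords[1], coords[0], indexing="ij")
    origins = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    cell_shape = [params.cell_size] * 3
    cell_shape[slicing_axis] = 1
    cell_shape_t = tuple(cell_shape)
    grid = CellGrid(
        volume_shape=shape,
        cell_shape=cell_shape_t,
        stride=tuple(1 if ax == slicing_axis else stride for ax in range(3)),
        origins=origins.astype(np.int64),
    )

    n_bins = params.n_dir2
    values = np.empty((len(dataset), grid.n_cells, n_bins))
    u_ax, v_ax = in_plane
    for i, vol in enumerate(dataset):
        data = np.asarray(vol.intensities, dtype=float)
        gu = _derivative(data, u_ax)
        gv = _derivative(data, v_ax)
        mag = np.hypot(gu, gv)
        theta = np.degrees(np.arctan2(gv, gu))
        theta = np.where(theta < 0.0, theta + 360.0, theta)
        theta = np.where(theta >= 360.0, 0.0, theta)
        bins = np.minimum(
            np.floor(theta / (360.0 / n_bins)).astype(np.int64), n_bins - 1
        )
        for c, origin in enumerate(grid.origins):
            sl = tuple(
                slice(int(o), int(o) + s)
                for o, s in zip(origin, cell_shape_t)
            )
            hist = np.bincount(
                np.ravel(bins[sl]), weights=np.ravel(mag[sl]),
                minlength=n_bins,
            )
            if params.normalize:
                norm = np.linalg.norm(hist)
                if norm >= _EPS:
                    hist = hist / norm
            values[i, c] = hist
    return FeatureTensor(
        values=values,
        grid=grid,
        params=params,
        subject_ids=[v.subject_id for v in dataset],
        labels=[v.label for v in dataset],
        affine=dataset.affine.copy(),
    )


# --- serialization ----------------------------------------------------------

def save_features(tensor: FeatureTensor, path: str) -> None:
    """Save a feature tensor as a compressed array container + JSON sidecar."""
    import json
    from pathlib import Path as _P

    np.savez_compressed(
        path,
        values=tensor.values,
        origins=tensor.grid.origins,
        affine=tensor.affine if tensor.affine is not None else np.eye(4),
    )
    meta = dict(
        volume_shape=list(tensor.grid.volume_shape),
        cell_shape=list(tensor.grid.cell_shape),
        stride=list(tensor.grid.stride),
        masked=tensor.grid.masked,
        n_dir2=tensor.params.n_dir2,
        scheme=tensor.params.scheme,
        cell_size=tensor.params.cell_size,
        overlap_fraction=tensor.params.overlap_fraction,
        normalize=tensor.params.normalize,
        subject_ids=tensor.subject_ids,
        labels=tensor.labels,
    )
    p = _P(str(path))
    if p.suffix != ".npz":
        p = p.with_suffix(p.suffix + ".npz")
    p.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_features(path: str) -> FeatureTensor:
    import json
    from pathlib import Path as _P

    p = _P(str(path))
    if p.suffix != ".npz":
        p = p.with_suffix(p.suffix + ".npz")
    arrays = np.load(p)
    meta = json.loads(p.with_suffix(".json").read_text())
    params = HOGParams(
        n_dir2=meta["n_dir2"],
        scheme=meta["scheme"],
        cell_size=meta["cell_size"],
        overlap_fraction=meta["overlap_fraction"],
        normalize=meta["normalize"],
    )
    grid = CellGrid(
        volume_shape=tuple(meta["volume_shape"]),
        cell_shape=tuple(meta["cell_shape"]),
        stride=tuple(meta["stride"]),
        origins=arrays["origins"],
        masked=meta.get("masked", False),
    )
    return FeatureTensor(
        values=arrays["values"],
        grid=grid,
        params=params,
        subject_ids=list(meta["subject_ids"]),
        labels=list(meta["labels"]),
        affine=arrays["affine"],
    )
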