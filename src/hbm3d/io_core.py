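"""Volume / atlas / dataset I/O and run configuration.

All coordinate conventions live here: voxel indices are 0-based, cell extents
are half-open ``[origin, origin + size)``, and MNI millimetre coordinates are
obtained by applying the NIfTI affine to 0-based voxel indices in homogeneous
coordinates. Volumes are assumed to be already segmented and spatially
normalized (e.g. by SPM12); no registration is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

ASD = "ASD"
HC = "HC"
UNKNOWN = "unknown"

VALID_LABELS = frozenset({ASD, HC, UNKNOWN})


class GeometryError(ValueError):
    """Shape or affine mismatch between volumes that must share a grid."""


class AtlasError(ValueError):
    """Malformed atlas label volume or name table."""


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


@dataclass
class BrainVolume:
    """A 3D intensity grid with a voxel-to-MNI affine and optional label.

    Parameters
    ----------
    intensities
        3D array of scalar intensities (arbitrary units).
    affine
        4x4 voxel-to-MNI millimetre transform (NIfTI convention, applied to
        0-based voxel indices).
    subject_id
        Free-form identifier.
    label
        One of ``"ASD"``, ``"HC"`` or ``"unknown"``.
    """

    intensities: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError(
                f"intensities must be a 3D grid with positive dimensions, "
                f"got shape {self.intensities.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class Dataset:
    """An ordered collection of volumes sharing one grid and affine."""

    volumes: list[BrainVolume]

    def __post_init__(self) -> None:
        if not self.volumes:
            raise GeometryError("dataset must contain at least one volume")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if v.shape != ref.shape:
                raise GeometryError(
                    f"volume {v.subject_id!r} shape {v.shape} differs from "
                    f"reference shape {ref.shape}"
                )
            if not np.allclose(v.affine, ref.affine):
                raise GeometryError(
                    f"volume {v.subject_id!r} affine differs from reference"
                )

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return Dataset([self.volumes[j] for j in i])
        return self.volumes[i]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def affine(self) -> np.ndarray:
        return self.volumes[0].affine

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.volumes]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.volumes:
            counts[v.label] = counts.get(v.label, 0) + 1
        return counts

    def require_both_classes(self) -> None:
        counts = self.class_counts
        if counts.get(ASD, 0) < 1 or counts.get(HC, 0) < 1:
            raise ValueError(
                f"training requires at least one subject per class, "
                f"got counts {counts}"
            )


@dataclass
class AtlasVolume:
    """Integer-coded parcellation on its own affine plus a code->name map.

    Code 0 is background. Every nonzero code present in the grid must have a
    name.
    """

    codes: np.ndarray
    affine: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3:
            raise AtlasError("atlas label volume must be 3D")
        if not np.issubdtype(self.codes.dtype, np.integer):
            rounded = np.rint(self.codes)
            if not np.allclose(self.codes, rounded):
                raise AtlasError("atlas label volume must be integer-coded")
            self.codes = rounded.astype(np.int64)
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.codes).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise AtlasError(
                f"atlas codes {sorted(missing)} present in the volume have no "
                f"entry in the name table"
            )


def read_volume(path: str | Path, label: str = UNKNOWN) -> BrainVolume:
    """Read a 3D NIfTI image.

    4D images with a singleton trailing dimension are squeezed to 3D; any
    other dimensionality raises.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    return BrainVolume(
        intensities=data,
        affine=np.asarray(img.affine),
        subject_id=Path(path).name.split(".")[0],
        label=label,
    )


def write_volume(volume: BrainVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(
        np.asarray(volume.intensities, dtype=np.float32), volume.affine
    )
    nib.save(img, str(path))


def load_dataset(
    paths: Sequence[str | Path], labels: Sequence[str]
) -> Dataset:
    """Load a dataset from per-subject NIfTI paths and class labels."""
    if len(paths) != len(labels):
        raise ValueError(
            f"got {len(paths)} paths but {len(labels)} labels"
        )
    if len(paths) == 0:
        raise GeometryError("cannot load an empty dataset")
    return Dataset([read_volume(p, label=l) for p, l in zip(paths, labels)])


def read_atlas(volume_path: str | Path, table_path: str | Path) -> AtlasVolume:
    """Read an integer parcellation volume plus its code/name TSV.

    The table must have columns ``code`` and ``name``; duplicate codes are an
    error.
    """
    img = nib.load(str(volume_path))
    codes = np.asarray(img.dataobj)
    table = pd.read_csv(table_path, sep="\t")
    for col in ("code", "name"):
        if col not in table.columns:
            raise AtlasError(f"atlas table must have a {col!r} column")
    if table["code"].duplicated().any():
        dupes = sorted(table.loc[table["code"].duplicated(), "code"])
        raise AtlasError(f"duplicate atlas codes in table: {dupes}")
    names = {int(c): str(n) for c, n in zip(table["code"], table["name"])}
    return AtlasVolume(codes=codes, affine=np.asarray(img.affine), names=names)


# --- run configuration ------------------------------------------------------

#: Preset instances: (clustering, regional classifier, partition scheme).
#: K-means pairs with nearest-centroid; hierarchical (Ward) with linear SVM.
INSTANCE_PRESETS: Mapping[str, tuple[str, str, str]] = {
    "KNS32": ("kmeans", "nearest_centroid", "full"),
    "KNS26": ("kmeans", "nearest_centroid", "pole_merged"),
    "HSS32": ("hierarchical", "linear_svm", "full"),
    "HSS26": ("hierarchical", "linear_svm", "pole_merged"),
}

_CONFIG_DEFAULTS = dict(
    instance="KNS26",
    clustering=None,
    regional=None,
    scheme=None,
    final_kernel="linear",
    n_dir2=8,
    cell_size=14,
    overlap_fraction=0.5,
    normalize=True,
    svm_c=1.0,
    nb_alpha=1.0,
    k_folds=10,
    n_runs=10,
    seed=20200508,
)


@dataclass
class RunConfig:
    """Fully resolved run configuration with all defaults filled."""

    instance: str = "KNS26"
    clustering: str = "kmeans"
    regional: str = "nearest_centroid"
    scheme: str = "pole_merged"
    final_kernel: str = "linear"
    n_dir2: int = 8
    cell_size: int = 14
    overlap_fraction: float = 0.5
    normalize: bool = True
    svm_c: float = 1.0
    nb_alpha: float = 1.0
    k_folds: int = 10
    n_runs: int = 10
    seed: int = 20200508
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration, resolving instance presets.

    A config may name a preset instance (``KNS32``, ``KNS26``, ``HSS32``,
    ``HSS26``) which fixes the clustering method, regional classifier and
    partition scheme; explicit ``clustering`` / ``regional`` / ``scheme`` keys
    override individual choices (instance then reported as ``custom``). An
    empty or absent config yields all defaults.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a YAML mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    merged = dict(_CONFIG_DEFAULTS)
    merged.update(raw)

    instance = merged["instance"]
    explicit = {k: raw.get(k) for k in ("clustering", "regional", "scheme")}
    if instance in INSTANCE_PRESETS:
        clustering, regional, scheme = INSTANCE_PRESETS[instance]
    elif instance == "custom":
        clustering, regional, scheme = "kmeans", "nearest_centroid", "pole_merged"
    else:
        raise ConfigError(
            f"unknown instance {instance!r}; expected one of "
            f"{sorted(INSTANCE_PRESETS)} or 'custom'"
        )
    customized = False
    for key, preset_val in zip(
        ("clustering", "regional", "scheme"), (clustering, regional, scheme)
    ):
        if explicit[key] is not None and explicit[key] != preset_val:
            customized = True
    if explicit["clustering"] is not None:
        clustering = explicit["clustering"]
    if explicit["regional"] is not None:
        regional = explicit["regional"]
    if explicit["scheme"] is not None:
        scheme = explicit["scheme"]
    if customized and instance in INSTANCE_PRESETS:
        instance = "custom"

    if clustering not in ("kmeans", "hierarchical"):
        raise ConfigError(f"unknown clustering method {clustering!r}")
    if regional not in ("nearest_centroid", "linear_svm"):
        raise ConfigError(f"unknown regional classifier {regional!r}")
    if scheme not in ("full", "pole_merged"):
        raise ConfigError(f"unknown partition scheme {scheme!r}")

    return RunConfig(
        instance=instance,
        clustering=clustering,
        regional=regional,
        scheme=scheme,
        final_kernel=str(merged["final_kernel"]),
        n_dir2=int(merged["n_dir2"]),
        cell_size=int(merged["cell_size"]),
        overlap_fraction=float(merged["overlap_fraction"]),
        normalize=bool(merged["normalize"]),
        svm_c=float(merged["svm_c"]),
        nb_alpha=float(merged["nb_alpha"]),
        k_folds=int(merged["k_folds"]),
        n_runs=int(merged["n_runs"]),
        seed=int(merged["seed"]),
    )
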