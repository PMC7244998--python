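"""Shared fixtures: small phantom cohorts generated at test time."""

import numpy as np
import pytest

from hbm3d import (
    HBMInstanceConfig,
    HOGParams,
    PhantomSpec,
    extract_features,
    generate_phantom_dataset,
)

PHANTOM_PARAMS = HOGParams(n_dir2=8, scheme="pole_merged", cell_size=12,
                           overlap_fraction=0.0)


@pytest.fixture(scope="session")
def small_phantom():
    """8 + 8 subjects on a 24-voxel cube with one strong anomaly cell."""
    spec = PhantomSpec(
        shape=(24, 24, 24), half_axes=(11.0, 11.0, 11.0),
        anomaly_cells=[(12, 0, 0)], effect_size=8.0,
        n_per_class=8, seed=7,
    )
    return generate_phantom_dataset(spec)


@pytest.fixture(scope="session")
def small_features(small_phantom):
    dataset, _ = small_phantom
    return extract_features(dataset, PHANTOM_PARAMS)


@pytest.fixture(scope="session")
def strong_phantom():
    """20 + 20 subjects, 48-voxel cube, two strong anomaly cells (defaults)."""
    spec = PhantomSpec(effect_size=8.0, n_per_class=20, seed=11)
    return generate_phantom_dataset(spec)


@pytest.fixture(scope="session")
def strong_features(strong_phantom):
    dataset, _ = strong_phantom
    return extract_features(dataset, PHANTOM_PARAMS)


@pytest.fixture(scope="session")
def null_phantom():
    """Same cohort geometry with zero anomaly amplitude."""
    spec = PhantomSpec(effect_size=0.0, n_per_class=20, seed=11)
    return generate_phantom_dataset(spec)


@pytest.fixture(scope="session")
def kns26():
    return HBMInstanceConfig.from_preset("KNS26")
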