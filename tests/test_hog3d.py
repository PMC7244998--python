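"""Orientation binning, gradient fields, cell grids, and descriptors.

The bin-assignment oracle used here is an independent brute-force
implementation: it enumerates explicit interval boundary lists for sectors
and polar bands and tests membership directly, never sharing arithmetic with
the implementation under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbm3d import (
    BrainVolume,
    HOGParams,
    assign_orientation_bin,
    bin_count,
    cell_histogram,
    compute_gradient_field,
    extract_features,
    extract_features_2d,
    make_cell_grid,
)
from hbm3d.hog3d import ParameterError, load_features, save_features
from hbm3d.io_core import Dataset, GeometryError


def oracle_bin(theta: float, phi: float, n2: int, scheme: str) -> int:
    """Brute-force boundary-membership reference for one direction."""
    sector_edges = [i * 360.0 / n2 for i in range(n2 + 1)]
    sector = next(s for s in range(n2)
                  if sector_edges[s] <= theta < sector_edges[s + 1])
    if scheme == "full":
        n_bands = n2 // 2
        edges = [i * 180.0 / n_bands for i in range(n_bands + 1)]
        band = next(b for b in range(n_bands)
                    if edges[b] <= phi < edges[b + 1]
                    or (b == n_bands - 1 and phi == 180.0))
        return band * n2 + sector
    cap = 180.0 / n2
    total = bin_count(n2, "pole_merged")
    if phi < cap:
        return 0
    if phi >= 180.0 - cap:
        return total - 1
    n_mid = n2 // 2 - 1
    edges = [cap + i * (180.0 - 2 * cap) / n_mid for i in range(n_mid + 1)]
    band = next(b for b in range(n_mid)
                if edges[b] <= phi < edges[b + 1])
    return 1 + band * n2 + sector


class TestBinCount:
    @pytest.mark.parametrize("n2,scheme,expected", [
        (8, "full", 32),
        (8, "pole_merged", 26),
        (2, "full", 2),
        (2, "pole_merged", 2),
        (4, "pole_merged", 6),  # 2 polar caps + 1 middle band x 4 sectors
        (4, "full", 8),
    ])
    def test_counts(self, n2, scheme, expected):
        assert bin_count(n2, scheme) == expected

    @pytest.mark.parametrize("n2", [1, 3, 7, 0, -2])
    def test_odd_or_small_rejected(self, n2):
        with pytest.raises(ParameterError):
            bin_count(n2, "full")


class TestAssignOrientationBin:
    @pytest.mark.parametrize("theta,phi,scheme,expected", [
        (123.0, 5.0, "pole_merged", 0),        # north cap
        (123.0, 176.0, "pole_merged", 25),     # south cap
        (0.0, 90.0, "full", 16),               # band 2, sector 0
        (45.0, 90.0, "full", 17),              # boundary theta -> sector 1
        (0.0, 90.0, "pole_merged", 9),         # middle band 1, sector 0
        (0.0, 180.0, "full", 24),              # closing polar boundary, sector 0
        (359.9, 0.0, "full", 7),
    ])
    def test_frozen_examples(self, theta, phi, scheme, expected):
        params = HOGParams(n_dir2=8, scheme=scheme)
        assert assign_orientation_bin(theta, phi, params) == expected

    @pytest.mark.parametrize("theta,phi", [(-1, 90), (360, 90), (0, -1),
                                           (0, 181)])
    def test_out_of_range_rejected(self, theta, phi):
        with pytest.raises(ValueError):
            assign_orientation_bin(theta, phi, HOGParams())

    @pytest.mark.parametrize("scheme", ["full", "pole_merged"])
    @pytest.mark.parametrize("n2", [2, 4, 8])
    def test_oracle_equivalence_and_completeness(self, scheme, n2):
        """1e5 random directions: agreement with the brute-force oracle,
        every bin hit, every index valid."""
        rng = np.random.default_rng(42)
        n = 100_000
        theta = rng.uniform(0.0, 360.0, n)
        # uniform on the sphere so polar caps are properly exercised
        phi = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
        params = HOGParams(n_dir2=n2, scheme=scheme)
        got = assign_orientation_bin(theta, phi, params)
        assert got.min() >= 0 and got.max() < params.n_dir3
        assert len(np.unique(got)) == params.n_dir3
        expected = np.array([oracle_bin(t, p, n2, scheme)
                             for t, p in zip(theta, phi)])
        np.testing.assert_array_equal(got, expected)

    @given(theta=st.floats(0, 360, exclude_max=True),
           phi=st.floats(0, 180))
    @settings(max_examples=200, derandomize=True)
    def test_always_valid_index(self, theta, phi):
        for scheme in ("full", "pole_merged"):
            params = HOGParams(n_dir2=8, scheme=scheme)
            idx = assign_orientation_bin(theta, phi, params)
            assert 0 <= idx < params.n_dir3


class TestGradientField:
    def test_constant_volume_is_flat(self):
        field = compute_gradient_field(np.full((8, 8, 8), 3.0))
        np.testing.assert_array_equal(field.magnitude, 0.0)
        np.testing.assert_array_equal(field.theta, 0.0)
        np.testing.assert_array_equal(field.phi, 90.0)

    def test_x_ramp(self):
        x = np.arange(10, dtype=float)
        vol = np.broadcast_to(x[:, None, None], (10, 10, 10)).copy()
        field = compute_gradient_field(vol)
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(field.magnitude[interior], 1.0)
        np.testing.assert_allclose(field.theta[interior], 0.0)
        np.testing.assert_allclose(field.phi[interior], 90.0)

    def test_z_ramp_points_to_pole(self):
        z = np.arange(10, dtype=float)
        vol = np.broadcast_to(z[None, None, :], (10, 10, 10)).copy()
        field = compute_gradient_field(vol)
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(field.phi[interior], 0.0)

    def test_azimuthal_equivariance_quarter_turn(self):
        """Rotating a linear ramp 90 degrees about z shifts the populated
        sector by n_dir2 / 4 in the full scheme, same polar band."""
        params = HOGParams(n_dir2=8, scheme="full", cell_size=6,
                           overlap_fraction=0.0)
        x = np.arange(12, dtype=float)
        ramp_x = np.broadcast_to(x[:, None, None], (12, 12, 12)).copy()
        ramp_y = np.rot90(ramp_x, k=1, axes=(0, 1)).copy()
        interior = (slice(3, 9),) * 3
        for ramp, expected_sector in ((ramp_x, 0), (ramp_y, 2)):
            field = compute_gradient_field(ramp)
            bins = assign_orientation_bin(field.theta[interior],
                                          field.phi[interior], params)
            assert set(np.unique(bins)) == {2 * 8 + expected_sector}


class TestCellGrid:
    def test_overlapping_grid_origins(self):
        grid = make_cell_grid((40, 40, 40), 20, 0.5)
        assert grid.stride == (10, 10, 10)
        per_axis = sorted(set(grid.origins[:, 0].tolist()))
        assert per_axis == [0, 10, 20]
        assert grid.n_cells == 27

    def test_single_cell(self):
        grid = make_cell_grid((10, 10, 10), 10, 0.5)
        assert grid.n_cells == 1
        np.testing.assert_array_equal(grid.origins, [[0, 0, 0]])

    def test_cell_larger_than_volume_rejected(self):
        with pytest.raises(GeometryError):
            make_cell_grid((8, 8, 8), 10, 0.0)

    def test_mask_drops_low_coverage_cells(self):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[:12] = True  # only cells fully in x < 12 have >= 50% coverage
        grid = make_cell_grid((24, 24, 24), 12, 0.0, mask=mask)
        assert grid.masked
        assert grid.n_cells == 4
        assert np.all(grid.origins[:, 0] == 0)

    def test_raster_order_x_fastest(self):
        grid = make_cell_grid((24, 24, 24), 12, 0.0)
        np.testing.assert_array_equal(
            grid.origins[:4],
            [[0, 0, 0], [12, 0, 0], [0, 12, 0], [12, 12, 0]],
        )


class TestCellHistogram:
    def test_zero_gradient_cell_stays_zero(self):
        field = compute_gradient_field(np.zeros((8, 8, 8)))
        params = HOGParams(cell_size=4)
        hist = cell_histogram(field, (0, 0, 0), params)
        np.testing.assert_array_equal(hist, 0.0)

    def test_single_voxel_normalizes_to_one_hot(self):
        params = HOGParams(cell_size=4)
        field = compute_gradient_field(np.zeros((8, 8, 8)))
        field.magnitude[1, 1, 1] = 3.7
        field.theta[1, 1, 1] = 10.0
        field.phi[1, 1, 1] = 90.0
        hist = cell_histogram(field, (0, 0, 0), params)
        assert np.isclose(hist.max(), 1.0)
        assert np.count_nonzero(hist) == 1

    def test_two_equal_votes_split_l2(self):
        params = HOGParams(cell_size=4)
        field = compute_gradient_field(np.zeros((8, 8, 8)))
        field.magnitude[1, 1, 1] = 2.0
        field.phi[1, 1, 1] = 5.0       # north cap
        field.magnitude[2, 2, 2] = 2.0
        field.phi[2, 2, 2] = 176.0     # south cap
        hist = cell_histogram(field, (0, 0, 0), params)
        nz = hist[hist > 0]
        np.testing.assert_allclose(nz, [1 / np.sqrt(2)] * 2)

    def test_out_of_bounds_cell_rejected(self):
        field = compute_gradient_field(np.zeros((8, 8, 8)))
        with pytest.raises(GeometryError):
            cell_histogram(field, (6, 0, 0), HOGParams(cell_size=4))


class TestExtractFeatures:
    def _dataset(self, n=3, shape=(24, 24, 24), seed=0):
        rng = np.random.default_rng(seed)
        vols = [BrainVolume(intensities=rng.normal(size=shape),
                            affine=np.eye(4), subject_id=f"s{i}",
                            label="HC")
                for i in range(n)]
        return Dataset(vols)

    def test_shape_contract(self):
        ds = self._dataset()
        params = HOGParams(n_dir2=8, scheme="pole_merged", cell_size=12,
                           overlap_fraction=0.5)
        tensor = extract_features(ds, params)
        assert tensor.values.shape == (3, 27, 26)

    def test_subject_order_equivariance(self):
        ds = self._dataset()
        params = HOGParams(cell_size=12, overlap_fraction=0.0)
        t1 = extract_features(ds, params)
        t2 = extract_features(Dataset(ds.volumes[::-1]), params)
        np.testing.assert_array_equal(t1.values, t2.values[::-1])

    def test_mass_conservation_unnormalized(self):
        """Descriptor sum equals the brute-force magnitude sum per cell."""
        ds = self._dataset(n=2)
        params = HOGParams(cell_size=12, overlap_fraction=0.5,
                           normalize=False)
        tensor = extract_features(ds, params)
        for i, vol in enumerate(ds):
            field = compute_gradient_field(vol)
            for c, origin in enumerate(tensor.grid.origins):
                sl = tuple(slice(int(o), int(o) + 12) for o in origin)
                np.testing.assert_allclose(
                    tensor.values[i, c].sum(), field.magnitude[sl].sum(),
                    rtol=1e-10)

    def test_normalized_rows_unit_or_zero(self, small_features):
        norms = np.linalg.norm(small_features.values, axis=2)
        assert np.all((np.abs(norms - 1.0) < 1e-9) | (norms == 0.0))

    def test_round_trip_serialization(self, tmp_path, small_features):
        path = tmp_path / "features.npz"
        save_features(small_features, str(path))
        back = load_features(str(path))
        np.testing.assert_array_equal(back.values, small_features.values)
        np.testing.assert_array_equal(back.grid.origins,
                                      small_features.grid.origins)
        assert back.labels == small_features.labels


class TestExtractFeatures2D:
    def test_constant_volume_all_zero(self):
        vols = [BrainVolume(intensities=np.full((16, 16, 4), 2.0),
                            affine=np.eye(4), label="HC")]
        params = HOGParams(cell_size=8, overlap_fraction=0.0)
        tensor = extract_features_2d(Dataset(vols), slicing_axis=2,
                                     params=params)
        np.testing.assert_array_equal(tensor.values, 0.0)
        assert tensor.values.shape[2] == 8  # n_dir2 bins per cell

    def test_in_plane_ramp_one_hot_at_zero_degrees(self):
        x = np.arange(16, dtype=float)
        vol = np.broadcast_to(x[:, None, None], (16, 16, 4)).copy()
        vols = [BrainVolume(intensities=vol, affine=np.eye(4), label="HC")]
        params = HOGParams(cell_size=8, overlap_fraction=0.0)
        tensor = extract_features_2d(Dataset(vols), slicing_axis=2,
                                     params=params)
        # interior cells: gradient is +x everywhere -> bin 0 only
        assert np.all(tensor.values[0, :, 0] > 0.99)
        np.testing.assert_allclose(tensor.values[0, :, 1:], 0.0, atol=1e-12)

    def test_cells_per_slice_layout(self):
        vols = [BrainVolume(intensities=np.zeros((16, 16, 4)),
                            affine=np.eye(4), label="HC")]
        params = HOGParams(cell_size=8, overlap_fraction=0.0)
        tensor = extract_features_2d(Dataset(vols), slicing_axis=2,
                                     params=params)
        assert tensor.n_cells == 4 * 2 * 2  # 4 slices x 2x2 squares
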