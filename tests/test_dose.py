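"""CEM43 dose accumulation, volumetry, reconstruction and comparisons."""

import warnings

import numpy as np
import pytest

from sonomark.dose import (
    DoseConfig,
    DoseMap,
    apparent_marker_size,
    cem43,
    compare_groups,
    dose_volume,
    edge_mean_temperature,
    max_unmasked_temperature,
    reconstruct_3d,
    significance_stars,
)
from sonomark.errors import DegenerateInputError
from sonomark.geometry import RegionSpec, ScanGrid, voxel_centers_in_region
from sonomark.thermometry import ThermalMapSeries

CFG = DoseConfig()


def _constant_dose(dT_C, minutes, n_frames=61):
    times = np.linspace(0, minutes * 60.0, n_frames)
    dT = np.full((n_frames, 1, 1), float(dT_C))
    return cem43(dT, times, CFG)[0, 0]


class TestCem43:
    def test_breakpoint_temperature_accumulates_real_time(self):
        # at exactly 43 degC, R^0 = 1: dose equals elapsed minutes
        assert _constant_dose(6.0, 240.0) == pytest.approx(240.0, rel=1e-9)

    def test_ten_degrees_above_folds_1024(self):
        # 53 degC for 240/1024 minutes (14.06 s) reaches the threshold
        assert _constant_dose(16.0, 240.0 / 1024.0) == pytest.approx(240.0, rel=1e-9)

    def test_baseline_temperature_dose(self):
        # 37 degC for one minute: 0.25^6 equivalent minutes
        assert _constant_dose(0.0, 1.0) == pytest.approx(2.441e-4, rel=1e-3)

    def test_monotone_in_temperature(self):
        times = np.linspace(0, 60, 21)
        rng = np.random.default_rng(0)
        dT = rng.uniform(0, 20, (21, 4, 4))
        base = cem43(dT, times, CFG)
        hotter = cem43(dT + 0.5, times, CFG)
        assert np.all(hotter >= base)

    def test_additive_over_time_segments(self):
        times = np.linspace(0, 90, 31)
        rng = np.random.default_rng(1)
        dT = rng.uniform(0, 18, (31, 3, 3))
        whole = cem43(dT, times, CFG)
        split = cem43(dT[:16], times[:16], CFG) + cem43(dT[15:], times[15:], CFG)
        np.testing.assert_allclose(whole, split, rtol=1e-12)


class TestDoseVolume:
    def test_sub_threshold_map_has_zero_volume(self):
        dm = DoseMap(values=np.full((5, 5, 5), 100.0), voxel_volume_mm3=1.56**3)
        assert dose_volume(dm, 240.0) == 0.0

    def test_voxelized_ellipsoid_matches_closed_form(self):
        """A super-threshold region shaped like the 12 x 12 x 8 mm design
        ellipsoid measures 0.60 ml on the 1.56 mm grid (3% tolerance)."""
        spacing = 1.56
        c = (np.arange(26) - 12.5) * spacing
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        inside = (X / 6) ** 2 + (Y / 6) ** 2 + (Z / 4) ** 2 <= 1.0
        dm = DoseMap(values=np.where(inside, 500.0, 1.0), voxel_volume_mm3=spacing**3)
        vol = dose_volume(dm, 240.0)
        assert vol == pytest.approx(inside.sum() * spacing**3 / 1000.0, rel=1e-12)
        assert vol == pytest.approx(0.6032, rel=0.03)

    def test_zero_threshold_counts_everything(self):
        dm = DoseMap(values=np.full((4, 4), 1e-6), voxel_volume_mm3=2.0)
        assert dose_volume(dm, 0.0) == pytest.approx(4 * 4 * 2.0 / 1000.0)

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        dm = DoseMap(values=rng.uniform(0, 500, (10, 10)), voxel_volume_mm3=1.0)
        vols = [dose_volume(dm, t) for t in (0, 100, 240, 400)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestReconstruction:
    # odd voxel count with the centre convention puts a column exactly on
    # the intersection line, so separable fields reconstruct exactly
    GRID = ScanGrid(fov_mm=101.4, n_rows=65, n_cols=65,
                    center_convention="voxel_center")

    def _planes_from(self, f):
        """Plane restrictions of a callable T(x, y, z); rows=y, cols=x|z."""
        cols = self.GRID.col_coords_mm()
        rows = self.GRID.row_coords_mm()
        X, Yc = np.meshgrid(cols, rows)
        coronal = f(X, Yc, np.zeros_like(X))
        Zs, Ys = np.meshgrid(cols, rows)
        sagittal = f(np.zeros_like(Zs), Ys, Zs)
        return coronal, sagittal

    def test_separable_field_reconstructed_exactly(self):
        def truth(x, y, z):
            return 20 * np.exp(-(x**2) / 60) * np.exp(-(y**2) / 80) * np.exp(-(z**2) / 40)

        coronal, sagittal = self._planes_from(truth)
        T3, meta = reconstruct_3d(coronal, sagittal, self.GRID, CFG)
        Xg, Yg, Zg = np.meshgrid(meta["x_mm"], meta["y_mm"], meta["z_mm"], indexing="ij")
        expected = truth(Xg, Yg, Zg)
        got = np.moveaxis(T3, 0, 1)  # (y, x, z) -> (x, y, z)
        mask = expected > 1.0  # away from the eps guard
        np.testing.assert_allclose(got[mask], expected[mask], rtol=1e-6)

    def test_gaussian_peak_and_width_recovered(self):
        def truth(x, y, z):
            return 30 * np.exp(-(x**2 + y**2) / 50) * np.exp(-(z**2) / 18)

        coronal, sagittal = self._planes_from(truth)
        T3, meta = reconstruct_3d(coronal, sagittal, self.GRID, CFG)
        assert T3.max() == pytest.approx(30.0, rel=0.05)
        z_profile = T3.max(axis=(0, 1))
        half = np.count_nonzero(z_profile >= 15.0) * self.GRID.in_plane_voxel_mm
        expected_fwhm = 2 * np.sqrt(18 * np.log(2))
        assert half == pytest.approx(expected_fwhm, rel=0.15)

    def test_zero_maps_give_zero_volume(self):
        zero = np.zeros((65, 65))
        T3, _ = reconstruct_3d(zero, zero, self.GRID, CFG)
        assert not T3.any()

    def test_inconsistent_profiles_warn_but_reconstruct(self):
        def truth(x, y, z):
            return 20 * np.exp(-(x**2 + y**2) / 50) * np.exp(-(z**2) / 18)

        coronal, sagittal = self._planes_from(truth)
        with pytest.warns(RuntimeWarning, match="disagree"):
            reconstruct_3d(coronal, 1.5 * sagittal, self.GRID, CFG)

    def test_flat_sagittal_reduces_to_coronal(self):
        """Where the sagittal profile equals the line profile (flat in z),
        the reconstruction returns the coronal map."""
        rows = self.GRID.row_coords_mm()
        n = self.GRID.n_cols
        line = 20 * np.exp(-(rows**2) / 80)
        coronal = np.tile(line[:, None], (1, n)) * np.exp(
            -(self.GRID.col_coords_mm()[None, :] ** 2) / 60
        )
        sagittal = np.tile(line[:, None], (1, n))
        T3, meta = reconstruct_3d(coronal, sagittal, self.GRID, CFG)
        csel = np.abs(self.GRID.col_coords_mm()) <= CFG.reconstruction_extent_mm / 2 + 1e-9
        rsel = np.abs(rows) <= CFG.reconstruction_extent_mm / 2 + 1e-9
        iz = int(np.argmin(np.abs(meta["z_mm"])))
        # comparison restricted to rows where the line profile is above the
        # small-denominator guard
        ok = line[rsel] > 0.05 * line.max() * 1.5
        np.testing.assert_allclose(
            T3[ok, :, iz], coronal[np.ix_(rsel, csel)][ok], rtol=1e-9
        )


class TestSummaryMetrics:
    def _series(self, dT):
        dT = np.asarray(dT, dtype=float)
        return ThermalMapSeries(
            dT=dT, times_s=np.arange(dT.shape[0], dtype=float),
            valid=np.ones_like(dT, bool), orientation="coronal",
            grid=ScanGrid(), effective_prf_coeff=0.0094,
        )

    def test_max_unmasked_plain(self):
        dT = np.zeros((1, 4, 4))
        dT[0, 1, 2] = 28.4
        sigma = np.full_like(dT, 0.5)
        assert max_unmasked_temperature(self._series(dT), sigma, 2.0) == 28.4

    def test_max_unmasked_excludes_hot_masked_voxel(self):
        dT = np.zeros((1, 4, 4))
        dT[0, 1, 2] = 35.0
        dT[0, 2, 2] = 20.0
        sigma = np.full_like(dT, 0.5)
        sigma[0, 1, 2] = 9.0  # hottest voxel fails the sigma rule
        assert max_unmasked_temperature(self._series(dT), sigma, 2.0) == 20.0

    def test_max_unmasked_all_masked_rejected(self):
        dT = np.zeros((1, 2, 2))
        with pytest.raises(DegenerateInputError):
            max_unmasked_temperature(self._series(dT), np.full_like(dT, 9.0), 2.0)

    def test_edge_mean_uniform_field(self, scan_grid):
        assert edge_mean_temperature(np.full((128, 128), 17.0), scan_grid) == 17.0

    def test_edge_mean_radial_field_matches_enumeration(self, scan_grid):
        """On dT = r the annulus mean equals the mean radius of the 28
        centres, computed here by direct enumeration."""
        cols = scan_grid.col_coords_mm()
        rows = scan_grid.row_coords_mm()
        R = np.hypot(cols[None, :], rows[:, None])
        voxels = voxel_centers_in_region(
            scan_grid, RegionSpec(kind="annulus", inner_diameter_mm=9, outer_diameter_mm=12)
        )
        expected = np.mean([np.hypot(rows[r], cols[c]) for r, c in voxels])
        assert edge_mean_temperature(R, scan_grid) == pytest.approx(expected, rel=1e-12)


class TestApparentSize:
    GRID = ScanGrid(fov_mm=49.92, n_rows=32, n_cols=32)

    def test_no_void(self):
        assert apparent_marker_size(np.ones((32, 32)), self.GRID) == (0.0, 0.0)

    def test_rectangular_void_extents(self):
        mag = np.ones((32, 32))
        mag[10:18, 12:16] = 0.0  # 8 rows x 4 cols
        w, L = apparent_marker_size(mag, self.GRID, background_level=1.0)
        assert w == pytest.approx(4 * 1.56, abs=1e-9)
        assert L == pytest.approx(8 * 1.56, abs=1e-9)

    def test_largest_of_multiple_voids_measured(self):
        mag = np.ones((32, 32))
        mag[4:6, 4:6] = 0.0
        mag[20:26, 20:24] = 0.0
        with pytest.warns(RuntimeWarning, match="largest"):
            w, L = apparent_marker_size(mag, self.GRID, background_level=1.0)
        assert L == pytest.approx(6 * 1.56, abs=1e-9)


class TestGroupComparison:
    def test_identical_groups(self):
        t, p, stars = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and stars == ""

    def test_large_shift_highly_significant(self):
        a = [1.0, 2.0, 3.0, 2.0, 1.5, 2.5]
        b = [x + 10 for x in a]
        t, p, stars = compare_groups(a, b)
        assert p < 0.001 and stars == "***"

    def test_welch_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        t, p, _ = compare_groups(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_star_coding_thresholds(self):
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(0.2) == ""

    def test_degenerate_zero_variance(self):
        t, p, _ = compare_groups([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)
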