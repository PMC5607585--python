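"""Heating simulation, calibration, rendering and cohort generation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from sonomark.dose import apparent_marker_size
from sonomark.errors import OutOfBoundsError, StabilityError
from sonomark.geometry import ScanGrid, marker_from_catalogue
from sonomark.phantom import (
    PhantomSpec,
    SignalModel,
    SimGrid3D,
    SonicationProtocol,
    TransducerModel,
    calibrate_source,
    make_phantom_cohort,
    map_peak,
    render_images,
    simulate_heating,
    _apply_psf,
    _slab_weights,
)
from sonomark.thermometry import (
    AcquisitionParams,
    ThermometryConfig,
    phase_to_temperature,
)

# a single stationary dwell point at (2.34, 0, 0) mm, which is a voxel
# centre of the default (corner-convention) simulation grid
STATIONARY = SonicationProtocol(
    circle_diameters_mm=(4.68,),
    duration_s=4.0,
    pre_sonication_delay_s=1.0,
    post_observation_s=1.0,
    points_per_circle=1,
    n_pattern_cycles=1,
)


class TestSimulateHeating:
    def test_zero_power_means_zero_field(self):
        proto = replace(STATIONARY, acoustic_power_W=0.0)
        field = simulate_heating(proto, TransducerModel(), PhantomSpec())
        assert field.peak() == 0.0

    def test_no_diffusion_stationary_point_integrates_exactly(self):
        """With D = 0 and a point-sampled source of amplitude A at a voxel
        centre, the peak is exactly A * duration."""
        phantom = PhantomSpec(thermal_diffusivity_mm2_s=0.0)
        trans = TransducerModel(source_scale=0.01)
        # centre-convention grid puts a voxel centre on the dwell point
        proto = replace(STATIONARY, circle_diameters_mm=(6.24,))
        grid = SimGrid3D(center_convention="voxel_center")
        field = simulate_heating(proto, trans, phantom, grid, source_profile="point")
        amplitude = 0.01 * proto.acoustic_power_W  # degC per second
        assert field.peak() == pytest.approx(amplitude * proto.duration_s, rel=1e-9)

    def test_heating_linear_in_absorption(self):
        one = simulate_heating(STATIONARY, TransducerModel(source_scale=0.01),
                               PhantomSpec(absorption_factor=1.0))
        two = simulate_heating(STATIONARY, TransducerModel(source_scale=0.01),
                               PhantomSpec(absorption_factor=2.0))
        # atol absorbs denormal rounding in the far Gaussian tails
        np.testing.assert_allclose(
            two.temperatures, 2 * one.temperatures, rtol=1e-12, atol=1e-300
        )

    def test_insulated_energy_budget(self):
        """Total heat rises only while the source is on and is conserved
        during cooling (reflecting boundaries)."""
        proto = replace(STATIONARY, post_observation_s=4.0)
        field = simulate_heating(proto, TransducerModel(source_scale=0.01), PhantomSpec())
        totals = field.temperatures.sum(axis=(1, 2, 3))
        assert np.all(np.diff(totals) >= -1e-9)
        son_end = np.searchsorted(field.times_s, proto.sonication_end_s)
        cooling = totals[son_end:]
        np.testing.assert_allclose(cooling, cooling[0], rtol=1e-9)

    def test_unstable_step_rejected(self):
        with pytest.raises(StabilityError):
            simulate_heating(
                STATIONARY, TransducerModel(), PhantomSpec(thermal_diffusivity_mm2_s=5.0),
                time_step_s=0.5,
            )

    def test_trajectory_must_fit_grid(self):
        proto = replace(STATIONARY, circle_diameters_mm=(90.0,))
        with pytest.raises(OutOfBoundsError):
            simulate_heating(proto, TransducerModel(), PhantomSpec())

    def test_frames_cover_protocol_timeline(self):
        field = simulate_heating(STATIONARY, TransducerModel(), PhantomSpec())
        assert field.times_s[0] == 0.0
        assert field.times_s[-1] == pytest.approx(STATIONARY.total_time_s)
        assert np.all(field.temperatures[0] == 0.0)


class TestCalibration:
    def test_target_reached_within_one_percent(self, full_study_field):
        field = full_study_field["field"]
        assert map_peak(field) == pytest.approx(30.0, rel=0.01)

    def test_scale_is_linear_in_target(self, mini_config):
        cfg = mini_config
        s30 = calibrate_source(30.0, cfg.protocol, cfg.transducer, PhantomSpec(),
                               cfg.sim_grid)
        s15 = calibrate_source(15.0, cfg.protocol, cfg.transducer, PhantomSpec(),
                               cfg.sim_grid)
        assert s15 == pytest.approx(s30 / 2, rel=1e-12)

    def test_zero_target_gives_zero_scale(self, mini_config):
        cfg = mini_config
        assert calibrate_source(0.0, cfg.protocol, cfg.transducer, PhantomSpec(),
                                cfg.sim_grid) == 0.0


class TestRendering:
    def test_cold_field_renders_flat_images(self, mini_config):
        cfg = mini_config
        proto = replace(cfg.protocol, acoustic_power_W=0.0)
        field = simulate_heating(proto, cfg.transducer, PhantomSpec(), cfg.sim_grid)
        imgs = render_images(field, None, SignalModel(baseline_snr=np.inf),
                             cfg.acq, cfg.scan_grid, rng_seed=0)
        cor = imgs["coronal"]
        np.testing.assert_allclose(
            cor.magnitudes, np.broadcast_to(cor.magnitudes[0], cor.magnitudes.shape),
            atol=1e-12,
        )
        np.testing.assert_allclose(np.diff(cor.phases, axis=0), 0.0, atol=1e-12)

    def test_prf_round_trip_recovers_imaged_field(self, mini_config):
        """Noiseless render followed by PRF conversion returns exactly the
        slab-averaged, PSF-convolved simulated temperature field."""
        cfg = mini_config
        scale = calibrate_source(30.0, cfg.protocol, cfg.transducer, PhantomSpec(),
                                 cfg.sim_grid)
        field = simulate_heating(cfg.protocol, replace(cfg.transducer, source_scale=scale),
                                 PhantomSpec(), cfg.sim_grid)
        imgs = render_images(field, None, SignalModel(baseline_snr=np.inf),
                             cfg.acq, cfg.scan_grid, rng_seed=0)
        tms = phase_to_temperature(imgs["coronal"], ThermometryConfig(),
                                   reference_frames=0)
        # independent expectation: slab weights + linear interpolation + PSF
        c = field.grid.coords()
        w = _slab_weights(c, field.grid.spacing_mm, cfg.scan_grid.slice_thickness_mm / 2)
        i = field.temperatures.shape[0] - 1
        slab = np.tensordot(field.temperatures[i], w, axes=([2], [0]))  # (x, y)
        interp = RegularGridInterpolator((c, c), slab, bounds_error=False, fill_value=0.0)
        X, Y = np.meshgrid(cfg.scan_grid.col_coords_mm(), cfg.scan_grid.row_coords_mm())
        expected = _apply_psf(interp(np.stack([X.ravel(), Y.ravel()], axis=1)).reshape(X.shape))
        # the two linear interpolators differ only at the simulated-volume
        # boundary, where the field is ~1e-7 degC
        np.testing.assert_allclose(tms.dT[i], expected, atol=1e-5)

    def test_marker_orientation_controls_apparent_width(self, full_study_field):
        """The elongated marker renders a 3.5 mm-wide void parallel to B0
        and a 6.5 mm-wide void orthogonal to it (one-voxel tolerance)."""
        cfg, field = full_study_field["config"], full_study_field["field"]
        signal = SignalModel(baseline_snr=np.inf)
        par = marker_from_catalogue("Visicoil 1.1x10")
        vert = marker_from_catalogue("Visicoil 1.1x10 V")
        w_par, _ = apparent_marker_size(
            render_images(field, par, signal, cfg.acq, cfg.scan_grid, 0)["coronal"]
            .magnitudes[0], cfg.scan_grid,
        )
        w_vert, _ = apparent_marker_size(
            render_images(field, vert, signal, cfg.acq, cfg.scan_grid, 0)["sagittal"]
            .magnitudes[0], cfg.scan_grid,
        )
        px = cfg.scan_grid.in_plane_voxel_mm
        assert abs(w_par - 3.5) <= px
        assert abs(w_vert - 6.5) <= px
        assert w_vert > w_par

    def test_masked_count_tracks_heating_without_noise(self, full_study_field):
        """With the T1 decay active the per-frame masked count never drops
        while the sonication runs."""
        from sonomark.masking import mask_frame, temperature_std_map

        cfg, field = full_study_field["config"], full_study_field["field"]
        marker = marker_from_catalogue("Gold Anchor 2.1x2.1")
        imgs = render_images(field, marker, SignalModel(baseline_snr=np.inf),
                             cfg.acq, cfg.scan_grid, rng_seed=0)
        cor = imgs["coronal"]
        sigma = temperature_std_map(cor.magnitudes, 1.0 / 50.0, cor.acq)
        counts = mask_frame(sigma, 2.0).reshape(cor.n_frames, -1).sum(axis=1)
        son = (cor.times_s >= cfg.protocol.pre_sonication_delay_s) & (
            cor.times_s <= cfg.protocol.sonication_end_s
        )
        assert counts[0] > 0  # the void masks voxels before any heating
        assert np.all(np.diff(counts[son]) >= 0)


class TestCohort:
    def test_zero_spread_cohort_is_uniform(self):
        cohort = make_phantom_cohort(5, absorption_sd=0.0, rng_seed=1)
        assert all(p.absorption_factor == 1.0 for p in cohort)

    def test_study_spread_reproduced(self):
        cohort = make_phantom_cohort(17, absorption_sd=0.046, rng_seed=7)
        factors = np.array([p.absorption_factor for p in cohort])
        assert 0.02 <= factors.std(ddof=1) <= 0.08
        assert np.all((factors >= 0.8) & (factors <= 1.2))

    def test_seed_reproducibility(self):
        a = make_phantom_cohort(6, 0.046, rng_seed=42)
        b = make_phantom_cohort(6, 0.046, rng_seed=42)
        assert a == b

    def test_sim_grid_conventions(self):
        corner = SimGrid3D(extent_mm=40, spacing_mm=1.56)
        assert 0.78 in np.round(corner.coords(), 2)
        centred = SimGrid3D(extent_mm=40, spacing_mm=1.56, center_convention="voxel_center")
        assert 0.0 in centred.coords()
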