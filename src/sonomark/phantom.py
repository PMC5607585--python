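"""Synthetic phantom sonications: heating simulation and MR rendering.

This module generates image data with the statistical and physical
structure the analysis pipeline assumes:

* volumetric heating from a focal spot swept along concentric circles
  (3/6/9 mm diameters, 40 W acoustic, 30 s), simulated with an explicit
  finite-difference heat equation — the bioheat equation without a
  perfusion term, since the medium is an agar gel.  The focal source is
  Gaussian transversely and Lorentzian axially (the on-axis intensity
  of a focused beam falls off as 1/(1+(z/zR)^2); a Gaussian axial
  profile lacks the tails that give the lesion its axial extent);
* a marker-induced signal void larger than the physical marker
  (apparent-size factors), modelled as a graded magnitude suppression
  whose 50% contour is the apparent-size ellipsoid;
* temperature-dependent signal decay through the ~1%/°C T1 increase in
  an SPGR steady-state signal model;
* independent complex Gaussian noise set by a baseline SNR.

The source amplitude is calibrated (by linearity) so the reference
phantom peaks at a prescribed temperature increase, 30 °C by default,
measured the way the study measures temperature: on the slab-averaged
coronal thermal map (set ``measure="field"`` for the 3D voxel peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import ndtr
from scipy.stats import truncnorm

from .errors import (
    CalibrationError,
    InvalidSpecError,
    OutOfBoundsError,
    StabilityError,
)
from .geometry import MarkerSpec, ScanGrid
from .thermometry import AcquisitionParams, ImageSeries, prf_rad_per_C

__all__ = [
    "SonicationProtocol",
    "TransducerModel",
    "PhantomSpec",
    "SignalModel",
    "SimGrid3D",
    "HeatingField",
    "simulate_heating",
    "calibrate_source",
    "map_peak",
    "render_images",
    "make_phantom_cohort",
    "spgr_signal",
]

#: -6 dB width to Gaussian sigma conversion (FWHM convention).
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# Fixed smooth phase baseline per slice (phantom study, short series: no
# drift model).  Coefficients of c0 + c1*u/100 + c2*v/100 + c3*u*v/1e4.
_PHASE_BASELINE = (0.3, 0.8, -0.5, 0.2)

# In-plane acquisition PSF: separable 3-tap Bartlett (triangular) kernel,
# ~1.5-pixel FWHM.  EPI readout apodization plus partial-volume averaging
# make thermal maps visibly softer than point samples of the temperature
# field; without this the rendered maps are sharper than every spatial
# relationship the modality can produce.
_PSF_KERNEL = np.array([0.25, 0.5, 0.25])


def _apply_psf(frames: np.ndarray) -> np.ndarray:
    """Separable in-plane PSF on a (..., rows, cols) stack."""
    out = ndimage.convolve1d(frames, _PSF_KERNEL, axis=-1, mode="nearest")
    return ndimage.convolve1d(out, _PSF_KERNEL, axis=-2, mode="nearest")


@dataclass(frozen=True)
class SonicationProtocol:
    """Sonication timing and trajectory: concentric coronal circles.

    The focal point dwells on ``points_per_circle`` points per circle,
    visited sequentially inner to outer, with dwell time proportional to
    the circle circumference; the full pattern is cycled
    ``n_pattern_cycles`` times over the sonication duration.
    """

    circle_diameters_mm: tuple[float, ...] = (3.0, 6.0, 9.0)
    acoustic_power_W: float = 40.0
    duration_s: float = 30.0
    pre_sonication_delay_s: float = 10.0
    post_observation_s: float = 60.0
    points_per_circle: int = 8
    n_pattern_cycles: int = 30
    dwell_schedule: str = "uniform_sequential"

    def __post_init__(self) -> None:
        d = self.circle_diameters_mm
        if any(b <= a for a, b in zip(d, d[1:])):
            raise InvalidSpecError("circle diameters must be strictly increasing")
        if min(self.duration_s, self.pre_sonication_delay_s, self.post_observation_s) < 0:
            raise InvalidSpecError("delay, duration and observation must be >= 0")
        if self.acoustic_power_W < 0:
            raise InvalidSpecError("acoustic power must be >= 0")
        if self.points_per_circle < 1 or self.n_pattern_cycles < 1:
            raise InvalidSpecError("points_per_circle and n_pattern_cycles must be >= 1")
        if self.dwell_schedule != "uniform_sequential":
            raise InvalidSpecError(f"unknown dwell schedule {self.dwell_schedule!r}")

    @property
    def total_time_s(self) -> float:
        return self.pre_sonication_delay_s + self.duration_s + self.post_observation_s

    @property
    def sonication_end_s(self) -> float:
        return self.pre_sonication_delay_s + self.duration_s


@dataclass(frozen=True)
class TransducerModel:
    """Focal-spot geometry and calibrated heating amplitude.

    ``source_scale`` converts acoustic power to a peak heating rate
    (°C/s per W at unit absorption); it is set by
    :func:`calibrate_source`.
    """

    focal_widths_mm: tuple[float, float, float] = (0.7, 0.7, 4.5)
    frequency_MHz: float = 1.45
    source_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.focal_widths_mm):
            raise InvalidSpecError("focal widths must be positive")
        if self.source_scale < 0:
            raise InvalidSpecError("source_scale must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """One agar-gel phantom: absorption efficiency, diffusivity, marker."""

    phantom_id: str = "phantom"
    absorption_factor: float = 1.0
    thermal_diffusivity_mm2_s: float = 0.14
    marker: MarkerSpec | None = None
    wire_thread: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.absorption_factor <= 0:
            raise InvalidSpecError("absorption_factor must be positive")
        if self.thermal_diffusivity_mm2_s < 0:
            raise InvalidSpecError("thermal diffusivity must be >= 0")


@dataclass(frozen=True)
class SignalModel:
    """Magnitude-signal model: SPGR with T1(T), void floor and noise.

    T1 rises by ``t1_temp_coeff`` (fraction per °C, 1%/°C) which decays
    the steady-state SPGR signal as temperature increases.  Set
    ``baseline_snr`` to ``inf`` for noiseless rendering.
    """

    baseline_snr: float = 50.0
    t1_temp_coeff: float = 0.01
    baseline_t1_ms: float = 1500.0
    void_floor_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_snr <= 0:
            raise InvalidSpecError("baseline_snr must be positive")
        if not 0 <= self.void_floor_fraction < 0.5:
            raise InvalidSpecError("void_floor_fraction must be in [0, 0.5)")
        if self.baseline_t1_ms <= 0:
            raise InvalidSpecError("baseline_t1_ms must be positive")


@dataclass(frozen=True)
class SimGrid3D:
    """Isotropic cubic simulation grid centred on the focus.

    With the default ``"voxel_corner"`` convention the origin is a
    voxel corner and centres lie at half-integer multiples of the
    spacing — the same lattice as the imaging grid, so rendering at
    matched spacing samples simulated voxels exactly instead of
    blurring them through interpolation.  ``"voxel_center"`` puts a
    voxel centre at the origin.
    """

    extent_mm: float = 40.0
    spacing_mm: float = 1.56
    center_convention: str = "voxel_corner"

    def __post_init__(self) -> None:
        if self.extent_mm <= 0 or self.spacing_mm <= 0:
            raise InvalidSpecError("grid extent and spacing must be positive")
        if self.center_convention not in ("voxel_corner", "voxel_center"):
            raise InvalidSpecError(
                f"unknown center convention {self.center_convention!r}"
            )

    @property
    def n(self) -> int:
        n = int(round(self.extent_mm / self.spacing_mm))
        if self.center_convention == "voxel_corner":
            return n if n % 2 == 0 else n + 1
        return n if n % 2 == 1 else n + 1

    def coords(self) -> np.ndarray:
        n = self.n
        if self.center_convention == "voxel_corner":
            return (np.arange(n) - n / 2 + 0.5) * self.spacing_mm
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing_mm


@dataclass
class HeatingField:
    """Simulated dT(x, y, z) snapshots at regular frame times."""

    temperatures: np.ndarray  # (n_frames, nx, ny, nz), °C above baseline
    times_s: np.ndarray
    grid: SimGrid3D
    frame_interval_s: float

    def peak(self) -> float:
        return float(self.temperatures.max(initial=0.0))


def _laplacian(T: np.ndarray, h: float) -> np.ndarray:
    """7-point Laplacian with reflecting (insulated) boundaries."""
    Tp = np.pad(T, 1, mode="edge")
    return (
        Tp[2:, 1:-1, 1:-1]
        + Tp[:-2, 1:-1, 1:-1]
        + Tp[1:-1, 2:, 1:-1]
        + Tp[1:-1, :-2, 1:-1]
        + Tp[1:-1, 1:-1, 2:]
        + Tp[1:-1, 1:-1, :-2]
        - 6.0 * T
    ) / h**2


def _trajectory_points(protocol: SonicationProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Dwell points (n, 3) in mm and per-point cycle-time fractions."""
    pts = []
    weights = []
    total_d = sum(protocol.circle_diameters_mm)
    ppc = protocol.points_per_circle
    for ci, d in enumerate(protocol.circle_diameters_mm):
        r = d / 2.0
        for j in range(ppc):
            theta = 2.0 * math.pi * (j + 0.5 * ci) / ppc
            pts.append((r * math.cos(theta), r * math.sin(theta), 0.0))
            weights.append(d / (total_d * ppc))
    return np.asarray(pts), np.asarray(weights)


def _source_profile(
    grid: SimGrid3D,
    center: np.ndarray,
    widths_mm: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Separable focal intensity profile (unit peak) on the grid.

    Transverse (x, y) axes are Gaussian with sigma = width / (2
    sqrt(2 ln 2)); the beam axis (z) is Lorentzian with half-maximum
    half-width zR = width / 2, matching the slow on-axis falloff of a
    focused beam.  ``"point"`` samples the profile at voxel centres;
    ``"voxel_mean"`` averages it analytically over each voxel, which
    keeps the total deposited power independent of the sub-voxel
    position of the focus (the focal spot is narrower than practical
    grid spacings).
    """
    c = grid.coords()
    h = grid.spacing_mm
    axes = []
    for ax in range(3):
        u = c - center[ax]
        if ax < 2:
            s = widths_mm[ax] * _FWHM_TO_SIGMA
            if mode == "point":
                axes.append(np.exp(-0.5 * (u / s) ** 2))
            elif mode == "voxel_mean":
                hi = ndtr((u + h / 2.0) / s)
                lo = ndtr((u - h / 2.0) / s)
                axes.append((hi - lo) * s * math.sqrt(2.0 * math.pi) / h)
            else:
                raise InvalidSpecError(f"unknown source profile mode {mode!r}")
        else:
            zr = widths_mm[ax] / 2.0
            if mode == "point":
                axes.append(1.0 / (1.0 + (u / zr) ** 2))
            else:
                hi = np.arctan((u + h / 2.0) / zr)
                lo = np.arctan((u - h / 2.0) / zr)
                axes.append((hi - lo) * zr / h)
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def _dwell_timeline(protocol: SonicationProtocol, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Start/end times of every dwell interval and its point index."""
    cycle_time = protocol.duration_s / protocol.n_pattern_cycles
    durs = np.tile(weights * cycle_time, protocol.n_pattern_cycles)
    idx = np.tile(np.arange(weights.size), protocol.n_pattern_cycles)
    ends = protocol.pre_sonication_delay_s + np.cumsum(durs)
    starts = ends - durs
    return starts, ends, idx


def simulate_heating(
    protocol: SonicationProtocol,
    transducer: TransducerModel,
    phantom: PhantomSpec,
    grid: SimGrid3D | None = None,
    time_step_s: float = 0.25,
    frame_interval_s: float = 0.5,
    source_profile: str = "voxel_mean",
) -> HeatingField:
    """Explicit finite-difference solution of dT/dt = D lap(T) + S(x, t).

    The source is a 3D Gaussian of the transducer's -6 dB focal widths
    centred on the scheduled trajectory point, active during the
    sonication window only, with peak amplitude
    ``source_scale * acoustic_power * absorption_factor`` (°C/s).
    Boundaries are insulated.  Deterministic given its inputs.
    """
    if grid is None:
        grid = SimGrid3D()
    D = phantom.thermal_diffusivity_mm2_s
    h = grid.spacing_mm
    # snap the step so frames land exactly on step boundaries
    steps_per_frame = max(1, int(math.ceil(frame_interval_s / time_step_s - 1e-12)))
    dt = frame_interval_s / steps_per_frame
    if D > 0 and dt > h**2 / (6.0 * D) + 1e-12:
        raise StabilityError(
            f"time step {dt:.3g} s exceeds stability bound "
            f"{h ** 2 / (6 * D):.3g} s for D={D} mm^2/s"
        )
    pts, weights = _trajectory_points(protocol)
    half = grid.extent_mm / 2.0
    if np.any(np.abs(pts) > half):
        raise OutOfBoundsError("sonication trajectory extends beyond the grid")

    amplitude = (
        transducer.source_scale * protocol.acoustic_power_W * phantom.absorption_factor
    )
    widths = np.asarray(transducer.focal_widths_mm)
    profiles = np.stack(
        [_source_profile(grid, p, widths, source_profile) for p in pts]
    )

    n_frames = int(round(protocol.total_time_s / frame_interval_s)) + 1
    n_steps = (n_frames - 1) * steps_per_frame
    starts, ends, pidx = _dwell_timeline(protocol, weights)

    # per-step source weights: fraction of the step spent on each point
    W = np.zeros((n_steps, pts.shape[0]))
    for s0, s1, p in zip(starts, ends, pidx):
        i0 = int(math.floor(s0 / dt))
        i1 = min(int(math.ceil(s1 / dt)), n_steps)
        for i in range(i0, i1):
            lo, hi = i * dt, (i + 1) * dt
            overlap = min(hi, s1) - max(lo, s0)
            if overlap > 0:
                W[i, p] += overlap / dt

    n = grid.n
    T = np.zeros((n, n, n))
    frames = np.empty((n_frames, n, n, n))
    frames[0] = T
    times = np.arange(n_frames) * frame_interval_s
    fi = 1
    for step in range(n_steps):
        dTdt = np.zeros_like(T) if amplitude == 0 else amplitude * np.tensordot(
            W[step], profiles, axes=(0, 0)
        )
        if D > 0:
            dTdt += D * _laplacian(T, h)
        T = T + dt * dTdt
        if (step + 1) % steps_per_frame == 0:
            frames[fi] = T
            fi += 1
    return HeatingField(
        temperatures=frames, times_s=times, grid=grid, frame_interval_s=frame_interval_s
    )


def map_peak(field: HeatingField, slab_thickness_mm: float = 5.0) -> float:
    """Peak temperature increase as monitored on the coronal thermal
    map: the maximum of the field averaged over the imaging slab and
    convolved with the in-plane acquisition PSF."""
    w = _slab_weights(field.grid.coords(), field.grid.spacing_mm, slab_thickness_mm / 2.0)
    coronal = np.tensordot(field.temperatures, w, axes=([3], [0]))
    return float(_apply_psf(coronal).max(initial=0.0))


def calibrate_source(
    target_peak_C: float,
    protocol: SonicationProtocol,
    transducer: TransducerModel,
    reference_phantom: PhantomSpec,
    grid: SimGrid3D | None = None,
    measure: str = "map",
    slab_thickness_mm: float = 5.0,
    **sim_kwargs,
) -> float:
    """Source scale making the reference simulation peak at the target.

    ``measure`` selects what "peak" means: ``"map"`` (default) is the
    peak on the slab-averaged coronal thermal map — the quantity the
    study monitors and the referent of the clinical 30 °C target —
    while ``"field"`` is the instantaneous 3D voxel maximum.  The
    heating field is exactly linear in the source amplitude, so a
    single simulation and a ratio suffice.
    """
    if target_peak_C < 0:
        raise InvalidSpecError("target peak must be >= 0")
    if measure not in ("map", "field"):
        raise InvalidSpecError(f"unknown peak measure {measure!r}")
    if target_peak_C == 0:
        return 0.0
    probe_scale = transducer.source_scale if transducer.source_scale > 0 else 1.0
    probe = replace(transducer, source_scale=probe_scale)
    field = simulate_heating(protocol, probe, reference_phantom, grid, **sim_kwargs)
    peak = field.peak() if measure == "field" else map_peak(field, slab_thickness_mm)
    if peak <= 0:
        raise CalibrationError("reference simulation produced no heating")
    return probe_scale * target_peak_C / peak


def spgr_signal(t1_ms: np.ndarray | float, tr_ms: float, flip_deg: float) -> np.ndarray:
    """SPGR steady-state signal sin(a)(1-E1)/(1-cos(a)E1), E1=exp(-TR/T1)."""
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    a = math.radians(flip_deg)
    return math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1)


def _void_multiplier(
    marker: MarkerSpec,
    signal: SignalModel,
    u: np.ndarray,
    v: np.ndarray,
    plane: str,
) -> np.ndarray:
    """Graded signal-void multiplier evaluated on a slice mid-plane.

    The void is an ellipsoid aligned with the marker axis (y for
    parallel_B0, z/anterior-posterior for orthogonal_B0) with semi-axes
    equal to apparent factor x physical dimension / 2.  The radial
    profile is ``1 - (1 - vf) exp(-a rho^2)`` with ``a = ln(2 (1-vf))``
    so the 50% magnitude contour falls exactly on the apparent-size
    ellipsoid and the floor at the core is ``vf``.

    ``u``/``v`` are in-plane mm coordinate grids: (x, y) for coronal at
    z=0, (z, y) for sagittal at x=0.
    """
    vf = signal.void_floor_fraction
    a_t = marker.apparent_width_factor * marker.width_mm / 2.0
    a_l = marker.apparent_length_factor * marker.length_mm / 2.0
    if marker.shape == "sphere":
        sx = sy = sz = a_t
    elif marker.orientation == "parallel_B0":
        sx, sy, sz = a_t, a_l, a_t
    else:  # orthogonal_B0: long axis anterior-posterior
        sx, sy, sz = a_t, a_t, a_l
    if plane == "coronal":  # z = 0
        rho2 = (u / sx) ** 2 + (v / sy) ** 2
    elif plane == "sagittal":  # x = 0
        rho2 = (u / sz) ** 2 + (v / sy) ** 2
    else:
        raise InvalidSpecError(f"unknown plane {plane!r}")
    decay = math.log(2.0 * (1.0 - vf))
    return 1.0 - (1.0 - vf) * np.exp(-decay * rho2)


def _slab_weights(coords: np.ndarray, spacing: float, half_thickness: float) -> np.ndarray:
    """Overlap fraction of each simulation voxel with the imaging slab."""
    lo = coords - spacing / 2.0
    hi = coords + spacing / 2.0
    overlap = np.clip(np.minimum(hi, half_thickness) - np.maximum(lo, -half_thickness), 0, None)
    total = overlap.sum()
    if total <= 0:
        raise OutOfBoundsError("imaging slab does not intersect the simulated volume")
    return overlap / total


def _resample_to_scan(
    frames_2d: np.ndarray,
    sim_coords_col: np.ndarray,
    sim_coords_row: np.ndarray,
    grid: ScanGrid,
) -> np.ndarray:
    """Bilinear resampling of (n_frames, n_u, n_v) simulation frames
    (axes = col-axis, row-axis in mm) onto the scan grid; zero outside."""
    h_c = sim_coords_col[1] - sim_coords_col[0]
    h_r = sim_coords_row[1] - sim_coords_row[0]
    ic = (grid.col_coords_mm() - sim_coords_col[0]) / h_c
    ir = (grid.row_coords_mm() - sim_coords_row[0]) / h_r
    IC, IR = np.meshgrid(ic, ir)  # (n_rows, n_cols)
    out = np.empty((frames_2d.shape[0], grid.n_rows, grid.n_cols))
    for t in range(frames_2d.shape[0]):
        out[t] = ndimage.map_coordinates(
            frames_2d[t], [IC, IR], order=1, mode="constant", cval=0.0
        )
    return out


def render_images(
    field: HeatingField,
    marker: MarkerSpec | None,
    signal: SignalModel,
    acq: AcquisitionParams,
    grid: ScanGrid | None = None,
    rng_seed: int = 0,
    prf_coeff_ppm_per_C: float = 0.0094,
) -> dict[str, ImageSeries]:
    """Render one coronal and one sagittal image series from a field.

    Per frame: the simulated dT is averaged over the 5 mm slab,
    resampled to the scan grid and convolved with the in-plane
    acquisition PSF; the magnitude is the SPGR signal ratio with T1(dT)
    (background normalised to 1), multiplied by the marker void profile
    (evaluated at the slice mid-plane, PSF-convolved once); the phase
    is a fixed smooth baseline plus k*dT; complex Gaussian noise of
    sigma 1/baseline_snr is added to both channels.

    With noise disabled (``baseline_snr = inf``) the rendering/PRF
    round trip is exact: ``phase_to_temperature`` recovers the
    slab-averaged field to float tolerance.
    """
    if grid is None:
        grid = ScanGrid()
    if acq.frame_interval_s != field.frame_interval_s:
        acq = replace(acq, frame_interval_s=field.frame_interval_s)
    k = prf_rad_per_C(acq, prf_coeff_ppm_per_C)
    c = field.grid.coords()
    half_slab = grid.slice_thickness_mm / 2.0
    wslab = _slab_weights(c, field.grid.spacing_mm, half_slab)
    rng = np.random.default_rng(rng_seed)
    noise_sigma = 0.0 if not np.isfinite(signal.baseline_snr) else 1.0 / signal.baseline_snr

    out: dict[str, ImageSeries] = {}
    for plane in ("coronal", "sagittal"):
        pgrid = replace(grid, orientation=plane)
        if plane == "coronal":
            # slab over z; image cols = x, rows = y
            dT2d = np.tensordot(field.temperatures, wslab, axes=([3], [0]))
        else:
            # slab over x; image cols = z, rows = y
            dT2d = np.tensordot(field.temperatures, wslab, axes=([1], [0]))
            dT2d = np.moveaxis(dT2d, 2, 1)  # (t, z, y) -> axes (col-axis, row-axis)
        dT_img = _apply_psf(_resample_to_scan(dT2d, c, c, pgrid))

        X = pgrid.col_coords_mm()[None, :]
        Y = pgrid.row_coords_mm()[:, None]
        t1 = signal.baseline_t1_ms * (1.0 + signal.t1_temp_coeff * dT_img)
        mag = spgr_signal(t1, acq.tr_ms, acq.flip_deg) / spgr_signal(
            signal.baseline_t1_ms, acq.tr_ms, acq.flip_deg
        )
        if marker is not None:
            U, V = np.meshgrid(pgrid.col_coords_mm(), pgrid.row_coords_mm())
            mag = mag * _apply_psf(_void_multiplier(marker, signal, U, V, plane))[None]
        phase0 = (
            _PHASE_BASELINE[0]
            + _PHASE_BASELINE[1] * X / 100.0
            + _PHASE_BASELINE[2] * Y / 100.0
            + _PHASE_BASELINE[3] * X * Y / 1e4
        )
        phase = phase0[None] + k * dT_img
        cplx = mag * np.exp(1j * phase)
        if noise_sigma > 0:
            cplx = cplx + rng.normal(0.0, noise_sigma, cplx.shape) + 1j * rng.normal(
                0.0, noise_sigma, cplx.shape
            )
        out[plane] = ImageSeries(
            magnitudes=np.abs(cplx),
            phases=np.angle(cplx),
            times_s=field.times_s.copy(),
            orientation=plane,
            grid=pgrid,
            acq=acq,
        )
    return out


def make_phantom_cohort(
    n: int,
    absorption_sd: float = 0.046,
    rng_seed: int = 0,
    markers: Sequence[MarkerSpec | None] | None = None,
    thermal_diffusivity_mm2_s: float = 0.14,
) -> list[PhantomSpec]:
    """Cohort of phantoms with absorption factors ~ N(1, sd) truncated
    to [0.8, 1.2]; reproducible under the seed."""
    if n < 1:
        raise InvalidSpecError("cohort size must be >= 1")
    if not 0 <= absorption_sd < 1:
        raise InvalidSpecError("absorption_sd must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    if absorption_sd == 0:
        factors = np.ones(n)
    else:
        a, b = (0.8 - 1.0) / absorption_sd, (1.2 - 1.0) / absorption_sd
        factors = truncnorm.rvs(a, b, loc=1.0, scale=absorption_sd, size=n, random_state=rng)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for i in range(n):
        marker = markers[i] if markers is not None else None
        cohort.append(
            PhantomSpec(
                phantom_id=f"phantom_{i:02d}" if marker is None else marker.name,
                absorption_factor=float(factors[i]),
                thermal_diffusivity_mm2_s=thermal_diffusivity_mm2_s,
                marker=marker,
                rng_seed=int(seeds[i]),
            )
        )
    return cohort
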